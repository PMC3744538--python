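"""Synthetic proteome and annotation worlds with planted ground truth.

The generator emulates the statistical structure the screening cascade
assumes, so that every stage is testable without any external database:

* a background of proteins with i.i.d. residues (uniform frequencies by
  default; a Swiss-Prot-like preset is provided) whose chance motif
  windows follow an exactly computable rate (:func:`expected_hit_rate`);
* a planted subset of "true substrates", each carrying exactly one
  exact instance of the kinase consensus and one of the PBD recognition
  motif at recorded, non-overlapping positions;
* near-miss decoys: background proteins that receive an exact kinase
  instance mutated at a single constrained non-phosphoacceptor position
  — the minimal perturbation separating the 0.8 and 1.0 similarity
  thresholds (such windows score exactly 5/6 on the default consensus);
* annotations: planted substrates always carry a cell-cycle phase label
  (drawn from a G2/M-weighted mixture, echoing the biology of a mitotic
  kinase) and, under the defaults, the enriched "cell cycle" biological-
  process term and a cancer-association term; background proteins
  receive each with small probability, plus uniformly assigned noise
  terms that carry no signal.

Setting ``q_pos`` or ``cancer_rate_pos`` below 1 models annotation-
database incompleteness: the screen's sensitivity for planted
substrates then degrades by roughly their product, since truly planted
but unannotated proteins are invisible to the annotation-driven stages.

Everything is reproducible: one seed determines the whole world, and
identical specs produce byte-identical FASTA/GMT/TSV outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .enrichment import GO_NAMESPACES, AnnotationSet
from .errors import DomainError
from .motifs import (
    AMINO_ACIDS,
    FULL_ALPHABET,
    KINASE_CONSENSUS,
    PBD_CONSENSUS,
    MotifPattern,
    compile_motif,
    matches_required,
)
from .pipeline import PHASES

_AA = np.frombuffer(AMINO_ACIDS.encode("ascii"), dtype=np.uint8)

#: Average Swiss-Prot residue frequencies (UniProtKB release statistics),
#: normalized to sum to 1; order follows :data:`poloscan.motifs.AMINO_ACIDS`.
SWISSPROT_FREQUENCIES = np.array(
    [
        0.0825, 0.0138, 0.0546, 0.0672, 0.0386, 0.0707, 0.0227, 0.0591,
        0.0580, 0.0965, 0.0241, 0.0406, 0.0474, 0.0393, 0.0553, 0.0665,
        0.0536, 0.0686, 0.0110, 0.0292,
    ]
)
SWISSPROT_FREQUENCIES = SWISSPROT_FREQUENCIES / SWISSPROT_FREQUENCIES.sum()

DEFAULT_PHASE_MIXTURE = {
    "G1": 0.15,
    "S": 0.15,
    "G2": 0.25,
    "M": 0.25,
    "cytokinesis": 0.10,
    "checkpoint": 0.10,
}

ENRICHED_TERM = ("biological_process", "cell cycle")
CANCER_TERM = ("cancer", "cancer-associated")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the simulated proteome/annotation world.

    ``length_mean``/``length_sd`` draw protein lengths from a normal
    distribution, clamped so both motifs fit with room to spare.  The
    default length (150 residues) keeps the similarity filter selective:
    at 80% identity a background protein of this length passes with
    probability ~0.4, so the cascade funnels the way the real screen
    did, rather than letting chance windows saturate stage ii.
    """

    n_proteins: int = 500
    n_planted: int = 50
    length_mean: float = 150.0
    length_sd: float = 50.0
    background_frequencies: np.ndarray = field(
        default_factory=lambda: np.full(20, 0.05)
    )
    near_miss_rate: float = 0.1
    phase_mixture: dict = field(default_factory=lambda: dict(DEFAULT_PHASE_MIXTURE))
    q_pos: float = 1.0
    q_neg: float = 0.05
    cancer_rate_pos: float = 1.0
    cancer_rate_neg: float = 0.05
    phase_rate_neg: float = 0.1
    n_noise_terms: int = 20
    noise_term_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_planted > self.n_proteins:
            raise DomainError(
                f"n_planted {self.n_planted} > n_proteins {self.n_proteins}"
            )
        if self.n_proteins < 0 or self.n_planted < 0 or self.n_noise_terms < 0:
            raise DomainError("counts must be non-negative")
        freqs = np.asarray(self.background_frequencies, dtype=float)
        if freqs.shape != (20,) or (freqs < 0).any():
            raise DomainError("background_frequencies must be 20 non-negative values")
        if abs(float(freqs.sum()) - 1.0) > 1e-9:
            raise DomainError("background_frequencies must sum to 1 within 1e-9")
        for label in (
            "near_miss_rate", "q_pos", "q_neg", "cancer_rate_pos",
            "cancer_rate_neg", "phase_rate_neg", "noise_term_rate",
        ):
            v = getattr(self, label)
            if not 0.0 <= v <= 1.0:
                raise DomainError(f"{label} {v} outside [0, 1]")
        mix = np.array([self.phase_mixture.get(p, 0.0) for p in PHASES], dtype=float)
        if (mix < 0).any() or abs(mix.sum() - 1.0) > 1e-9:
            raise DomainError("phase_mixture must be a probability vector over "
                              + ", ".join(PHASES))

    @property
    def frequencies(self) -> np.ndarray:
        return np.asarray(self.background_frequencies, dtype=float)


@dataclass(frozen=True)
class PlantedSubstrate:
    """Ground-truth bookkeeping for one planted protein (1-based starts)."""

    protein_id: str
    kinase_start: int
    kinase_window: str
    pbd_start: int
    pbd_window: str
    phases: tuple
    terms: tuple


@dataclass
class GroundTruth:
    planted: list
    near_miss_ids: frozenset = frozenset()

    @property
    def ids(self) -> frozenset:
        return frozenset(p.protein_id for p in self.planted)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "protein_id": p.protein_id,
                    "kinase_start": p.kinase_start,
                    "kinase_window": p.kinase_window,
                    "pbd_start": p.pbd_start,
                    "pbd_window": p.pbd_window,
                    "phases": ";".join(p.phases),
                    "terms": ";".join(f"{ns}:{t}" for ns, t in p.terms),
                }
                for p in self.planted
            ],
            columns=[
                "protein_id", "kinase_start", "kinase_window",
                "pbd_start", "pbd_window", "phases", "terms",
            ],
        )


def _sample_instance(motif: MotifPattern, rng, freqs: np.ndarray) -> str:
    """An exact motif instance; wildcard residues follow the background."""
    out = []
    for allowed in motif.positions:
        if allowed == FULL_ALPHABET:
            out.append(AMINO_ACIDS[rng.choice(20, p=freqs)])
        else:
            choices = sorted(allowed)
            out.append(choices[rng.integers(len(choices))])
    return "".join(out)


def _near_miss_instance(motif: MotifPattern, rng, freqs: np.ndarray) -> str:
    """Exact instance mutated at one constrained non-phospho position."""
    window = list(_sample_instance(motif, rng, freqs))
    constrained = [
        i
        for i in range(motif.length)
        if motif.positions[i] != FULL_ALPHABET and i != motif.phospho_index - 1
    ]
    if not constrained:
        raise DomainError("motif has no constrained non-phospho position to mutate")
    i = constrained[rng.integers(len(constrained))]
    outside = sorted(set(AMINO_ACIDS) - motif.positions[i])
    window[i] = outside[rng.integers(len(outside))]
    return "".join(window)


def _draw_from(mapping: dict, rng) -> str:
    keys = [p for p in PHASES if mapping.get(p, 0.0) > 0]
    probs = np.array([mapping[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


def generate_world(spec: SyntheticSpec):
    """Build (proteome records, annotations, ground truth) from a spec.

    Deterministic for a fixed spec (including its seed).  Planted
    proteins are the first ``n_planted`` records; each receives exactly
    one exact kinase-consensus instance and one exact PBD instance at
    non-overlapping recorded positions, written over the background
    residues in place.
    """
    from .io import ProteinRecord

    spec.validate()
    rng = np.random.default_rng(spec.seed)
    freqs = spec.frequencies
    kinase = compile_motif(KINASE_CONSENSUS, name="kinase")
    pbd = compile_motif(PBD_CONSENSUS, name="pbd")
    min_len = kinase.length + pbd.length + 10

    lengths = np.maximum(
        np.rint(rng.normal(spec.length_mean, spec.length_sd, spec.n_proteins)).astype(int),
        min_len,
    )

    records = []
    planted: list[PlantedSubstrate] = []
    near_miss_ids = set()
    assignments: dict[str, set] = {}

    for i in range(spec.n_proteins):
        pid = f"SYN{i + 1:04d}"
        length = int(lengths[i])
        codes = rng.choice(20, size=length, p=freqs)
        terms: set = set()

        if i < spec.n_planted:
            kin_start = int(rng.integers(0, length - kinase.length + 1))
            candidates = [
                s
                for s in range(length - pbd.length + 1)
                if s + pbd.length <= kin_start or s >= kin_start + kinase.length
            ]
            pbd_start = int(candidates[rng.integers(len(candidates))])
            kin_window = _sample_instance(kinase, rng, freqs)
            pbd_window = _sample_instance(pbd, rng, freqs)
            for off, ch in enumerate(kin_window):
                codes[kin_start + off] = AMINO_ACIDS.index(ch)
            for off, ch in enumerate(pbd_window):
                codes[pbd_start + off] = AMINO_ACIDS.index(ch)

            phase = _draw_from(spec.phase_mixture, rng)
            terms.add(("phase", phase))
            if rng.random() < spec.q_pos:
                terms.add(ENRICHED_TERM)
            if rng.random() < spec.cancer_rate_pos:
                terms.add(CANCER_TERM)
            planted.append(
                PlantedSubstrate(
                    protein_id=pid,
                    kinase_start=kin_start + 1,
                    kinase_window=kin_window,
                    pbd_start=pbd_start + 1,
                    pbd_window=pbd_window,
                    phases=(phase,),
                    terms=tuple(sorted(terms)),
                )
            )
        else:
            if rng.random() < spec.near_miss_rate:
                nm_window = _near_miss_instance(kinase, rng, freqs)
                nm_start = int(rng.integers(0, length - kinase.length + 1))
                for off, ch in enumerate(nm_window):
                    codes[nm_start + off] = AMINO_ACIDS.index(ch)
                near_miss_ids.add(pid)
            if rng.random() < spec.q_neg:
                terms.add(ENRICHED_TERM)
            if rng.random() < spec.phase_rate_neg:
                terms.add(("phase", PHASES[rng.integers(len(PHASES))]))
            if rng.random() < spec.cancer_rate_neg:
                terms.add(CANCER_TERM)

        records.append(ProteinRecord(pid, _AA[codes].tobytes().decode("ascii")))
        if terms:
            assignments[pid] = terms

    # uniform noise terms over random GO namespaces: no enrichment signal
    for j in range(spec.n_noise_terms):
        ns = GO_NAMESPACES[rng.integers(len(GO_NAMESPACES))]
        mask = rng.random(spec.n_proteins) < spec.noise_term_rate
        for i in np.nonzero(mask)[0]:
            assignments.setdefault(f"SYN{i + 1:04d}", set()).add(
                (ns, f"module_{j:02d}")
            )

    annotations = AnnotationSet(assignments)
    truth = GroundTruth(planted=planted, near_miss_ids=frozenset(near_miss_ids))
    return records, annotations, truth


def window_match_probability(
    motif: MotifPattern, min_similarity: float, frequencies=None
) -> float:
    """Exact probability that one i.i.d. background window qualifies.

    The phosphoacceptor is forced to match (hard constraint); the
    similarity threshold allows ``length - ceil(min_similarity*length)``
    mismatches, which can only occur at constrained non-phospho
    positions since wildcards always match.  Summing over every subset
    of those positions allowed to mismatch gives the exact rate — e.g.
    for the default kinase consensus under uniform frequencies this is
    (2/20)(2/20)(4/20)(1/20) = 1e-4 at threshold 1.0, and 33x that at
    0.8 (one mismatch allowed among the three non-phospho constrained
    positions: 1 + 18/2 + 16/4 + 19/1 = 33).
    """
    if frequencies is None:
        frequencies = np.full(20, 0.05)
    freqs = {aa: float(p) for aa, p in zip(AMINO_ACIDS, np.asarray(frequencies))}
    pi = motif.phospho_index - 1
    p_acceptor = sum(freqs[r] for r in motif.positions[pi])
    constrained = [
        i
        for i in range(motif.length)
        if i != pi and motif.positions[i] != FULL_ALPHABET
    ]
    match_p = [sum(freqs[r] for r in motif.positions[i]) for i in constrained]
    allowed_mismatches = motif.length - matches_required(motif.length, min_similarity)
    total = 0.0
    for m in range(min(allowed_mismatches, len(constrained)) + 1):
        for mismatched in combinations(range(len(constrained)), m):
            prod = 1.0
            for j, p in enumerate(match_p):
                prod *= (1.0 - p) if j in mismatched else p
            total += prod
    return p_acceptor * total


def expected_hit_rate(
    spec: SyntheticSpec, motif: MotifPattern, min_similarity: float
) -> float:
    """Expected qualifying windows per background protein of mean length."""
    n_windows = max(0.0, spec.length_mean - motif.length + 1)
    return n_windows * window_match_probability(
        motif, min_similarity, spec.frequencies
    )


def expected_background_final_rate(spec: SyntheticSpec, config=None) -> float:
    """Analytic per-background-protein probability of surviving all stages.

    Composes per-stage marginals assuming independence between stages
    and between windows: the stage-ii pass probability treats windows as
    independent (overlap correlations are slightly conservative), stage
    iii counts only the planted-term route with the enriched cluster
    retained (noise-cluster leakage adds roughly ``alpha *
    noise_term_rate * n_noise_terms`` and is included), stages iv/v use
    the chance-PBD and annotation rates directly.  Intended as a 3-SD
    oracle for the cascade's specificity, not an exact value.
    """
    from .pipeline import PipelineConfig

    if config is None:
        config = PipelineConfig()
    kinase, pbd_motif = config.compiled_motifs()
    n_windows = max(0, int(round(spec.length_mean)) - kinase.length + 1)
    p_win = window_match_probability(kinase, config.min_similarity, spec.frequencies)
    p_chance = 1.0 - (1.0 - p_win) ** n_windows
    p_ii = spec.near_miss_rate + (1.0 - spec.near_miss_rate) * p_chance

    p_noise_leak = 1.0 - (
        1.0 - spec.noise_term_rate * config.enrichment_alpha
    ) ** spec.n_noise_terms
    p_iii = 1.0 - (1.0 - spec.q_neg) * (1.0 - p_noise_leak)

    n_pbd_windows = max(0, int(round(spec.length_mean)) - pbd_motif.length + 1)
    p_pbd_win = window_match_probability(pbd_motif, 1.0, spec.frequencies)
    p_iv = 1.0 - (1.0 - p_pbd_win) ** n_pbd_windows

    p_v = spec.phase_rate_neg * spec.cancer_rate_neg
    return p_ii * p_iii * p_iv * p_v
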