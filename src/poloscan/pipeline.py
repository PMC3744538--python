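"""The staged substrate-screening cascade.

Candidate substrates of a kinase are isolated from a proteome by five
nested filters, mirroring how dual-recognition kinases such as Plk1
select targets (a kinase-domain phosphorylation consensus plus a
polo-box-domain docking site primed by another kinase):

  i.   the protein holds at least one kinase-consensus window whose
       phosphoacceptor (S/T) matches — any similarity;
  ii.  the best window reaches the similarity threshold (default 0.80,
       inclusive, which for the 6-position consensus admits exactly one
       mismatch outside the phosphoacceptor);
  iii. the protein belongs to at least one annotation cluster retained
       by the hypergeometric enrichment filter (clusters are built from
       the stage-ii survivor cohort against the annotated universe);
  iv.  the protein carries the PBD recognition motif, matched exactly —
       a similarity threshold on a 3-mer with one constrained position
       would be meaningless;
  v.   the protein is annotated in every required namespace (cell-cycle
       phase and cancer association by default).

Stage sets are nested, so per-stage survivor counts are non-increasing.
Final candidates are ranked deterministically (best similarity, then
strongest cluster, then PBD-site count, then identifier) and labelled
with their cell-cycle phases.

Note that stage iii is cohort-relative: enrichment is computed on the
stage-ii survivor set, so changing the upstream threshold changes the
cluster statistics, not merely the membership.  The cascade is monotone
in the enrichment threshold alpha, but not, in general, in
``min_similarity`` (admitting more background dilutes every cluster).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .enrichment import (
    GO_NAMESPACES,
    NAMESPACES,
    AnnotationSet,
    Cluster,
    cluster_proteins,
    filter_clusters,
)
from .errors import ConfigError, DomainError
from .motifs import (
    KINASE_CONSENSUS,
    PBD_CONSENSUS,
    MotifHit,
    compile_motif,
    matches_required,
    scan_proteome,
)

logger = logging.getLogger(__name__)

PHASES = ("G1", "S", "G2", "M", "cytokinesis", "checkpoint")

_PHASE_ALIASES = {
    "g1": ("G1",),
    "s": ("S",),
    "g2": ("G2",),
    "m": ("M",),
    "mitosis": ("M",),
    "g1/s": ("G1", "S"),
    "g2/m": ("G2", "M"),
    "cytokinesis": ("cytokinesis",),
    "checkpoint": ("checkpoint",),
    "checkpoints": ("checkpoint",),
}


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and motifs of the screening cascade.

    Defaults are the screen's published operating point: the Plk1 kinase
    consensus, the PBD recognition motif with its third position read as
    "any residue" (``pbd_strict=True`` restricts it to proline), a 0.80
    similarity floor and a 0.1 enrichment cutoff.
    """

    kinase_motif: str = KINASE_CONSENSUS
    pbd_motif: str = PBD_CONSENSUS
    min_similarity: float = 0.80
    scan_mode: str = "identity"
    enrichment_alpha: float = 0.1
    enrichment_namespaces: tuple = GO_NAMESPACES
    required_namespaces: tuple = ("phase", "cancer")
    pbd_strict: bool = False
    min_cluster_members: int = 3
    min_gap: int | None = None
    max_gap: int | None = None
    random_seed: int | None = None

    def validate(self) -> None:
        """Raise :class:`ConfigError` listing every violation at once."""
        problems = []
        if not 0.0 <= self.min_similarity <= 1.0:
            problems.append(f"min_similarity {self.min_similarity} outside [0, 1]")
        if not 0.0 < self.enrichment_alpha <= 1.0:
            problems.append(f"enrichment_alpha {self.enrichment_alpha} outside (0, 1]")
        if self.scan_mode not in ("identity", "substitution"):
            problems.append(f"scan_mode {self.scan_mode!r} not identity|substitution")
        if self.min_cluster_members < 1:
            problems.append(f"min_cluster_members {self.min_cluster_members} < 1")
        for ns in tuple(self.enrichment_namespaces) + tuple(self.required_namespaces):
            if ns not in NAMESPACES:
                problems.append(f"unknown namespace {ns!r}")
        if (self.min_gap is None) != (self.max_gap is None):
            problems.append("min_gap and max_gap must be set together")
        if self.min_gap is not None and self.max_gap is not None:
            if self.min_gap > self.max_gap:
                problems.append(f"min_gap {self.min_gap} > max_gap {self.max_gap}")
        for motif_field in ("kinase_motif", "pbd_motif"):
            try:
                compile_motif(getattr(self, motif_field))
            except Exception as exc:  # noqa: BLE001 - collected into one report
                problems.append(f"{motif_field}: {exc}")
        if problems:
            raise ConfigError(problems)

    def compiled_motifs(self):
        kinase = compile_motif(self.kinase_motif, name="kinase")
        pbd = compile_motif(
            self.pbd_motif, name="pbd", bracket_x_wildcard=not self.pbd_strict
        )
        return kinase, pbd

    def to_dict(self) -> dict:
        return {
            "kinase_motif": self.kinase_motif,
            "pbd_motif": self.pbd_motif,
            "min_similarity": self.min_similarity,
            "scan_mode": self.scan_mode,
            "enrichment_alpha": self.enrichment_alpha,
            "enrichment_namespaces": list(self.enrichment_namespaces),
            "required_namespaces": list(self.required_namespaces),
            "pbd_strict": self.pbd_strict,
            "min_cluster_members": self.min_cluster_members,
            "min_gap": self.min_gap,
            "max_gap": self.max_gap,
            "random_seed": self.random_seed,
        }


@dataclass
class CandidateRecord:
    """One protein's provenance through the cascade.

    Stage flags are monotone: a later flag can only be true when all
    earlier ones are.  ``rank`` is assigned iff all flags are true.
    """

    protein_id: str
    kinase_hits: list[MotifHit] = field(default_factory=list)
    pbd_hits: list[MotifHit] = field(default_factory=list)
    best_similarity: float = 0.0
    clusters: tuple = ()  # (namespace, term, p_value) triples, retained only
    phases: frozenset = frozenset()
    cancer_flag: bool = False
    has_kinase_motif: bool = False
    passed_similarity: bool = False
    passed_enrichment: bool = False
    has_pbd_motif: bool = False
    passed_annotation: bool = False
    rank: int | None = None

    @property
    def stage_flags(self) -> tuple[bool, ...]:
        return (
            self.has_kinase_motif,
            self.passed_similarity,
            self.passed_enrichment,
            self.has_pbd_motif,
            self.passed_annotation,
        )

    @property
    def min_cluster_p(self) -> float:
        return min((p for _, _, p in self.clusters), default=float("inf"))


@dataclass(frozen=True)
class StageCounts:
    """Distinct proteins surviving each stage, in cascade order."""

    kinase_motif: int
    similarity: int
    enrichment: int
    pbd_motif: int
    annotation: int

    def as_tuple(self) -> tuple[int, ...]:
        return (
            self.kinase_motif,
            self.similarity,
            self.enrichment,
            self.pbd_motif,
            self.annotation,
        )

    @property
    def non_increasing(self) -> bool:
        t = self.as_tuple()
        return all(a >= b for a, b in zip(t, t[1:]))


@dataclass
class ScreenResult:
    """Everything :func:`run_screen` produces."""

    records: list[CandidateRecord]
    candidates: list[CandidateRecord]  # final, ranked
    stage_counts: StageCounts
    clusters: list[Cluster]  # retained by the enrichment filter
    all_clusters: list[Cluster]


def assign_phases(candidate, annotations: AnnotationSet) -> frozenset:
    """Normalized cell-cycle phase labels of a candidate.

    Accepts a :class:`CandidateRecord` or a bare protein id.  Phase
    terms are normalized to the closed vocabulary {G1, S, G2, M,
    cytokinesis, checkpoint}; composite labels like "G2/M" expand to
    both phases.  A term outside the vocabulary is an error naming the
    term; a candidate with no phase term yields an empty set with a
    warning.
    """
    pid = candidate.protein_id if hasattr(candidate, "protein_id") else str(candidate)
    phases: set[str] = set()
    for term in annotations.terms_of(pid, "phase"):
        expansion = _PHASE_ALIASES.get(term.strip().lower())
        if expansion is None:
            raise DomainError(f"phase term {term!r} outside vocabulary {PHASES}")
        phases.update(expansion)
    if not phases:
        logger.warning("candidate %s carries no cell-cycle phase annotation", pid)
    return frozenset(phases)


def rank_candidates(candidates) -> list[CandidateRecord]:
    """Stable deterministic ranking of final candidates.

    Sort key: descending best similarity, ascending minimum cluster
    p-value, descending number of PBD sites, ascending protein id.
    Ranks are assigned 1..m on copies of the records.
    """
    ordered = sorted(
        candidates,
        key=lambda c: (-c.best_similarity, c.min_cluster_p, -len(c.pbd_hits), c.protein_id),
    )
    return [replace(c, rank=i) for i, c in enumerate(ordered, start=1)]


def _spacing_ok(record: CandidateRecord, min_gap: int, max_gap: int) -> bool:
    """Some kinase/PBD hit pair separated by a gap within [min_gap, max_gap].

    The gap counts residues strictly between the two windows; 0 means
    adjacent, overlapping windows have no (non-negative) gap.
    """
    for kh in record.kinase_hits:
        for ph in record.pbd_hits:
            gap = max(ph.start - kh.end - 1, kh.start - ph.end - 1)
            if gap >= 0 and min_gap <= gap <= max_gap:
                return True
    return False


def run_screen(
    proteome, annotations: AnnotationSet, config: PipelineConfig | None = None
) -> ScreenResult:
    """Run the full five-stage cascade over a proteome.

    Deterministic for fixed inputs and config.  Configuration problems
    (motifs that do not compile, unknown namespaces) are reported before
    any scanning.
    """
    if config is None:
        config = PipelineConfig()
    config.validate()
    kinase, pbd = config.compiled_motifs()
    # namespaces missing from the annotation set contribute no clusters;
    # all of them missing is a misconfiguration worth stopping for
    effective_namespaces = tuple(
        ns for ns in config.enrichment_namespaces if ns in annotations.namespaces
    )
    if not effective_namespaces:
        raise ConfigError(
            [
                "none of the enrichment namespaces "
                f"{tuple(config.enrichment_namespaces)} is present in the annotations"
            ]
        )

    # stage i: any kinase-consensus window with a matching phosphoacceptor
    kin_scan = scan_proteome(proteome, kinase, min_similarity=0.0, mode=config.scan_mode)
    by_protein = kin_scan.hits_by_protein()
    records = {
        pid: CandidateRecord(
            protein_id=pid,
            kinase_hits=hits,
            best_similarity=max(h.similarity for h in hits),
            has_kinase_motif=True,
        )
        for pid, hits in by_protein.items()
    }
    stage1 = set(records)

    # stage ii: similarity threshold on the best window
    needed = matches_required(kinase.length, config.min_similarity)
    stage2 = {
        pid
        for pid, rec in records.items()
        if round(rec.best_similarity * kinase.length) >= needed
    }
    for pid in stage2:
        records[pid].passed_similarity = True

    # stage iii: enrichment clusters over the stage-ii cohort
    all_clusters = cluster_proteins(
        stage2,
        annotations,
        namespaces=effective_namespaces,
        min_members=config.min_cluster_members,
    )
    retained = filter_clusters(all_clusters, alpha=config.enrichment_alpha)
    retained_membership: dict[str, list] = {}
    for c in retained:
        for pid in c.members:
            retained_membership.setdefault(pid, []).append((c.namespace, c.term, c.p_value))
    stage3 = set(retained_membership) & stage2
    for pid in stage3:
        rec = records[pid]
        rec.passed_enrichment = True
        rec.clusters = tuple(sorted(retained_membership[pid], key=lambda t: (t[2], t[1])))

    # stage iv: exact PBD recognition motif (optionally spacing-constrained)
    pbd_scan = scan_proteome(proteome, pbd, min_similarity=1.0, mode="identity")
    pbd_by_protein = pbd_scan.hits_by_protein()
    for pid, hits in pbd_by_protein.items():
        if pid in records:
            records[pid].pbd_hits = hits
    stage4 = {pid for pid in stage3 if records[pid].pbd_hits}
    if config.min_gap is not None:
        stage4 = {
            pid
            for pid in stage4
            if _spacing_ok(records[pid], config.min_gap, config.max_gap)
        }
    for pid in stage4:
        records[pid].has_pbd_motif = True

    # stage v: required annotation namespaces (phase + cancer by default)
    stage5 = {
        pid
        for pid in stage4
        if all(annotations.is_annotated(pid, (ns,)) for ns in config.required_namespaces)
    }
    for pid in stage5:
        rec = records[pid]
        rec.passed_annotation = True
        rec.phases = assign_phases(rec, annotations)
        rec.cancer_flag = annotations.is_annotated(pid, ("cancer",))

    finals = rank_candidates([records[pid] for pid in stage5])
    for rec in finals:
        records[rec.protein_id] = rec

    counts = StageCounts(
        kinase_motif=len(stage1),
        similarity=len(stage2),
        enrichment=len(stage3),
        pbd_motif=len(stage4),
        annotation=len(stage5),
    )
    ordered_records = [records[pid] for pid in sorted(records)]
    return ScreenResult(
        records=ordered_records,
        candidates=finals,
        stage_counts=counts,
        clusters=retained,
        all_clusters=all_clusters,
    )


def build_phase_groups(candidates) -> dict[str, set[str]]:
    """Group ranked candidates by phase label (multi-membership allowed).

    The checkpoint group is kept separate from the true phases, matching
    how phase-wise substrate subnetworks are usually drawn.
    """
    groups: dict[str, set[str]] = {}
    for c in candidates:
        for phase in c.phases:
            groups.setdefault(phase, set()).add(c.protein_id)
    return groups
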