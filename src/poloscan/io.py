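"""File formats: FASTA proteomes, GMT annotation sets, TSV tables.

All writers are deterministic — stable column order, ``%.6g`` float
formatting, LF line endings — so identical inputs and seeds produce
byte-identical outputs.  GMT lines are ``term<TAB>namespace<TAB>member
ids...``: the description column carries the annotation namespace,
which is all the flat-label enrichment model needs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import NamedTuple

import pandas as pd
import yaml

from .enrichment import NAMESPACES, AnnotationSet
from .errors import ConfigError, ParseError
from .pipeline import PipelineConfig


class ProteinRecord(NamedTuple):
    id: str
    seq: str


def read_fasta(path) -> list[ProteinRecord]:
    """Read a multi-record FASTA file.

    Sequences are uppercased and concatenated across wrapped lines; the
    record id is the first whitespace-delimited token of the header.
    Structural problems (sequence before any header, empty id,
    duplicate id) raise :class:`ParseError` with a line number.
    """
    from Bio.SeqIO.FastaIO import SimpleFastaParser

    path = Path(path)
    seen: dict[str, int] = {}
    header_seen = False
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">") and not header_seen:
                raise ParseError("sequence data before first header", path, lineno)
            if stripped.startswith(">"):
                header_seen = True
                header = stripped[1:].strip()
                if not header:
                    raise ParseError("empty FASTA header", path, lineno)
                pid = header.split()[0]
                if pid in seen:
                    raise ParseError(
                        f"duplicate record id {pid!r} (first seen line {seen[pid]})",
                        path,
                        lineno,
                    )
                seen[pid] = lineno
    records = []
    with open(path) as handle:
        for title, seq in SimpleFastaParser(handle):
            records.append(ProteinRecord(title.split()[0], seq.upper()))
    return records


def write_fasta(path, records, width: int = 60) -> None:
    with open(path, "w", newline="\n") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            seq = str(rec.seq)
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def read_gmt(path, universe_size: int | None = None) -> AnnotationSet:
    """Read a GMT annotation file into an :class:`AnnotationSet`.

    Each line: ``term<TAB>namespace<TAB>member ids...``.  Unknown
    namespaces and short lines raise :class:`ParseError` with a line
    number.  An empty file yields a valid empty annotation set.
    """
    path = Path(path)
    assignments: dict[str, set] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"expected >= 3 tab-separated fields, got {len(fields)}",
                    path,
                    lineno,
                )
            term, namespace, *members = fields
            if namespace not in NAMESPACES:
                raise ParseError(f"unknown namespace {namespace!r}", path, lineno)
            if not term:
                raise ParseError("empty term", path, lineno)
            for pid in members:
                if pid:
                    assignments.setdefault(pid, set()).add((namespace, term))
    return AnnotationSet(assignments, universe_size=universe_size)


def write_gmt(path, annotations: AnnotationSet) -> None:
    with open(path, "w", newline="\n") as handle:
        for (ns, term), members in annotations.terms():
            handle.write("\t".join([term, ns, *sorted(members)]) + "\n")


_CONFIG_FIELDS = {f.name: f for f in dataclasses.fields(PipelineConfig)}


def load_config(path=None) -> PipelineConfig:
    """Load a YAML key-value config; unspecified keys take the defaults.

    Unknown keys and out-of-range values are collected and reported
    together in a single :class:`ConfigError`.
    """
    data = {}
    if path is not None:
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        if not isinstance(data, dict):
            raise ConfigError([f"config root must be a mapping, got {type(data).__name__}"])
    problems = [f"unknown config key {k!r}" for k in data if k not in _CONFIG_FIELDS]
    kwargs = {}
    for key, value in data.items():
        if key in _CONFIG_FIELDS:
            if key in ("enrichment_namespaces", "required_namespaces"):
                value = tuple(value) if value is not None else ()
            kwargs[key] = value
    if problems:
        raise ConfigError(problems)
    config = PipelineConfig(**kwargs)
    config.validate()  # raises ConfigError listing all violations
    return config


def sha256_of(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


@dataclasses.dataclass
class RunManifest:
    """Provenance of one run: config, input digests, seed, versions."""

    config: dict
    inputs: dict
    seed: int | None
    version: str
    timestamp: str
    stage_counts: dict | None = None

    @classmethod
    def create(cls, config, input_paths, seed=None, stage_counts=None):
        from . import __version__

        cfg = config.to_dict() if hasattr(config, "to_dict") else dict(config)
        return cls(
            config=cfg,
            inputs={str(p): sha256_of(p) for p in input_paths},
            seed=seed,
            version=__version__,
            timestamp=datetime.now(timezone.utc).isoformat(),
            stage_counts=stage_counts,
        )

    def write(self, path) -> None:
        with open(path, "w", newline="\n") as handle:
            json.dump(dataclasses.asdict(self), handle, indent=2, sort_keys=True)
            handle.write("\n")


def _write_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g", lineterminator="\n")


def write_hits(path, scan_result) -> None:
    _write_tsv(scan_result.to_frame(), path)


def write_clusters(path, clusters) -> None:
    frame = pd.DataFrame(
        [
            {
                "namespace": c.namespace,
                "term": c.term,
                "N": c.N,
                "K": c.K,
                "n": c.n,
                "k": c.k,
                "p_value": c.p_value,
                "members": ";".join(sorted(c.members)),
            }
            for c in clusters
        ],
        columns=["namespace", "term", "N", "K", "n", "k", "p_value", "members"],
    )
    _write_tsv(frame, path)


def write_candidates(path, records) -> None:
    frame = pd.DataFrame(
        [
            {
                "protein_id": r.protein_id,
                "rank": r.rank if r.rank is not None else "",
                "best_similarity": r.best_similarity,
                "n_kinase_hits": len(r.kinase_hits),
                "kinase_phosphosites": ";".join(
                    str(h.phospho_position) for h in r.kinase_hits
                ),
                "n_pbd_hits": len(r.pbd_hits),
                "pbd_sites": ";".join(str(h.start) for h in r.pbd_hits),
                "min_cluster_p": (
                    r.min_cluster_p if r.clusters else ""
                ),
                "clusters": ";".join(f"{ns}:{t}" for ns, t, _ in r.clusters),
                "phases": ";".join(sorted(r.phases)),
                "cancer": int(r.cancer_flag),
                "has_kinase_motif": int(r.has_kinase_motif),
                "passed_similarity": int(r.passed_similarity),
                "passed_enrichment": int(r.passed_enrichment),
                "has_pbd_motif": int(r.has_pbd_motif),
                "passed_annotation": int(r.passed_annotation),
            }
            for r in records
        ],
        columns=[
            "protein_id", "rank", "best_similarity", "n_kinase_hits",
            "kinase_phosphosites", "n_pbd_hits", "pbd_sites", "min_cluster_p",
            "clusters", "phases", "cancer", "has_kinase_motif",
            "passed_similarity", "passed_enrichment", "has_pbd_motif",
            "passed_annotation",
        ],
    )
    _write_tsv(frame, path)


def write_stage_counts(path, stage_counts) -> None:
    labels = [
        ("kinase_motif", "proteins with a kinase-consensus window"),
        ("similarity", "best window at or above the similarity threshold"),
        ("enrichment", "member of a retained enrichment cluster"),
        ("pbd_motif", "carries the PBD recognition motif"),
        ("annotation", "annotated in all required namespaces"),
    ]
    frame = pd.DataFrame(
        [
            {"stage": name, "description": desc, "count": getattr(stage_counts, name)}
            for name, desc in labels
        ],
        columns=["stage", "description", "count"],
    )
    _write_tsv(frame, path)


def write_phase_groups(path, groups) -> None:
    frame = pd.DataFrame(
        [
            {
                "phase": phase,
                "n_proteins": len(members),
                "members": ";".join(sorted(members)),
            }
            for phase, members in sorted(groups.items())
        ],
        columns=["phase", "n_proteins", "members"],
    )
    _write_tsv(frame, path)
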