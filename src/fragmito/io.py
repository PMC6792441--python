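"""File formats and pipeline configuration.

Internal coordinates are 0-based half-open on the forward strand
everywhere in the package; conversion to 1-based inclusive happens only
here, at the GFF3 boundary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("fragmito")

SCHEMA_VERSION = "1.0"


class FastaError(ValueError):
    pass


class GffError(ValueError):
    pass


class ConfigError(ValueError):
    pass


def read_fasta(path, alphabet: str | None = None) -> dict[str, str]:
    """Read FASTA into an ordered ``{id: sequence}`` mapping.

    Ids are taken up to the first whitespace; sequences are uppercased.
    Duplicate ids, empty files and (optionally) out-of-alphabet characters
    raise :class:`FastaError`.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FastaError(f"duplicate FASTA id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if alphabet is not None:
            bad = set(seq) - set(alphabet)
            if bad:
                raise FastaError(
                    f"record {rec.id!r} contains illegal character(s) {sorted(bad)!r}"
                )
        records[rec.id] = seq
    if not records:
        raise FastaError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Mapping[str, str], path, wrap: int = 60) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(recs)


def read_coverage_tsv(path) -> dict[str, float]:
    """Read a 2-column (contig_id, mean_coverage) TSV; header optional."""
    cov: dict[str, float] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ConfigError(f"{path}:{ln}: expected 2 tab-separated columns")
            if ln == 1 and parts[0].lower() in {"contig", "contig_id", "id"}:
                continue
            cov[parts[0]] = float(parts[1])
    if not cov:
        raise ConfigError(f"no coverage rows found in {path}")
    return cov


def write_coverage_tsv(coverage: Mapping[str, float], path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\tmean_coverage\n")
        for cid, c in coverage.items():
            fh.write(f"{cid}\t{c:.4f}\n")


@dataclass(frozen=True)
class GffFeature:
    """One GFF3 row carried with internal (0-based half-open) coordinates."""

    seqid: str
    type: str
    start: int
    end: int
    strand: str = "."
    score: float | None = None
    source: str = "fragmito"
    frame: str = "."
    attributes: Mapping[str, object] = field(default_factory=dict)


def write_gff3(
    features: Iterable[GffFeature],
    path,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Emit GFF3 (1-based inclusive) with a version pragma."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            if f.start < 0 or f.end <= f.start:
                raise GffError(f"feature on {f.seqid} has invalid interval [{f.start},{f.end})")
            if contig_lengths is not None:
                L = contig_lengths.get(f.seqid)
                if L is not None and f.end > L:
                    raise GffError(
                        f"feature on {f.seqid} ends at {f.end} beyond contig length {L}"
                    )
            score = "." if f.score is None else f"{f.score:g}"
            attrs = ";".join(f"{k}={v}" for k, v in f.attributes.items()) or "."
            fh.write(
                f"{f.seqid}\t{f.source}\t{f.type}\t{f.start + 1}\t{f.end}\t"
                f"{score}\t{f.strand}\t{f.frame}\t{attrs}\n"
            )


def read_gff3(path) -> list[GffFeature]:
    feats = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise GffError(f"malformed GFF3 row: {line!r}")
            attrs = {}
            if parts[8] != ".":
                for kv in parts[8].split(";"):
                    if kv:
                        k, _, v = kv.partition("=")
                        attrs[k] = v
            feats.append(
                GffFeature(
                    seqid=parts[0],
                    source=parts[1],
                    type=parts[2],
                    start=int(parts[3]) - 1,
                    end=int(parts[4]),
                    score=None if parts[5] == "." else float(parts[5]),
                    strand=parts[6],
                    frame=parts[7],
                    attributes=attrs,
                )
            )
    return feats


def write_report(obj, path) -> None:
    """Write a schema-versioned JSON report with stable key order."""
    payload = {"schema_version": SCHEMA_VERSION, "report": obj}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def read_report(path):
    with open(path) as fh:
        payload = json.load(fh)
    return payload["report"]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    if hasattr(obj, "tolist"):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"cannot serialize {type(obj)!r}")


# ---------------------------------------------------------------------------
# pipeline configuration


@dataclass
class PipelineConfig:
    """All tunables of the analysis pipeline, with field-level defaults.

    An empty config file is valid; unknown keys are rejected so typos fail
    loudly.  CLI flags override file values which override these defaults.
    """

    seed: int = 0
    log_level: str = "INFO"
    # genetic codes
    mito_table_id: int = 4
    nuclear_table_id: int = 1
    # module finding
    min_score: float = 55.0
    min_identity: float = 0.35
    min_module_aa: int = 5
    max_gap_aa: int = 10
    # cassette screen
    cassette_min_len: int = 80
    cassette_min_ident: float = 0.75
    cassette_max_ident: float = 0.995
    mito_min_len: int = 500
    cassette_search_window: int = 250
    # classification
    r_min: float = 3.0
    gc_delta: float = 0.05
    # SOM
    som_width: int = 20
    som_height: int = 12
    som_epochs: int = 10
    som_min_len: int = 500
    # chaining / refinement
    max_overlap_aa: int = 5
    extend_max_aa: int = 10
    k_max: int = 12
    u_gap_max_aa: int = 4
    # introns / U1
    max_intron_bp: int = 2000
    intron_search_bp: int = 6
    u1_min_identity: float = 0.7
    u1_min_len: int = 80
    u1_window_offset: int = 2  # recognition region = u1[offset : offset+9]
    u1_window_len: int = 9

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config {path} must be a flat key-value mapping")
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: Mapping[str, object]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)  # type: ignore[arg-type]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def log_effective(self) -> None:
        for k, v in sorted(self.to_dict().items()):
            logger.info("param %s = %r", k, v)
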