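"""Sequence I/O, result tables, and run configuration.

This module fixes the conventions used everywhere else in the package:

* Coordinates are **1-based, fully closed** intervals, so an interval
  ``(start, stop)`` has length ``stop - start + 1``.
* Sequences are accepted in DNA or RNA alphabet; all miRNA arithmetic is
  done after normalising ``T -> U`` and uppercasing.  Output sequences that
  describe miRNAs or precursors are written in the RNA alphabet.
* Result tables are tab-separated files with a header row; floats are
  rendered with three decimals.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "SeqRecord",
    "RunConfig",
    "FastaError",
    "ConfigError",
    "read_fasta",
    "write_fasta",
    "write_table",
    "read_table",
    "load_config",
    "interval_length",
    "revcomp",
    "to_rna",
    "to_dna",
]

_RNA_COMPLEMENT = str.maketrans("ACGUNRYSWKMBDHV", "UGCANYRSWMKVHDB")
_DNA_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")
_IUPAC = set("ACGTUNRYSWKMBDHV")


class FastaError(ValueError):
    """Malformed FASTA input (empty sequence, duplicate id, ...)."""


class ConfigError(ValueError):
    """Invalid run configuration (unknown key or out-of-range value)."""


def to_rna(seq: str) -> str:
    """Uppercase and convert to the RNA alphabet (T -> U)."""
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    """Uppercase and convert to the DNA alphabet (U -> T)."""
    return seq.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    """Reverse complement, preserving the input alphabet (DNA or RNA)."""
    s = seq.upper()
    table = _RNA_COMPLEMENT if "U" in s and "T" not in s else _DNA_COMPLEMENT
    return s.translate(table)[::-1]


@dataclass(frozen=True)
class SeqRecord:
    """A named nucleotide sequence (EST, unigene, mature miRNA, transcript)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaError("sequence record with empty id")
        if not self.seq:
            raise FastaError(f"sequence record {self.id!r} has empty sequence")
        bad = set(self.seq.upper()) - _IUPAC
        if bad:
            raise FastaError(
                f"record {self.id!r} contains non-nucleotide characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def rna(self) -> str:
        return to_rna(self.seq)

    def reverse_complement(self) -> "SeqRecord":
        return dataclasses.replace(self, seq=revcomp(self.seq))


def interval_length(start: int, stop: int) -> int:
    """Length of a 1-based fully closed interval: ``stop - start + 1``."""
    if start < 1 or stop < start:
        raise ValueError(f"invalid 1-based interval ({start}, {stop})")
    return stop - start + 1


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a FASTA file into a list of :class:`SeqRecord`.

    Order is preserved and sequences are uppercased.  Duplicate ids and
    empty sequences are fatal; the error names the offending record.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        if len(rec.seq) == 0:
            raise FastaError(f"record {rec.id!r} in {path} has empty sequence")
        records.append(SeqRecord(id=rec.id, seq=str(rec.seq).upper(), description=desc))
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def write_table(rows: Sequence, path: str | Path, schema: Sequence[str]) -> None:
    """Write records as a TSV with header; floats rendered with 3 decimals.

    ``rows`` may contain dicts or dataclass instances; every row must carry
    every schema column.
    """
    dict_rows = []
    for row in rows:
        d = dataclasses.asdict(row) if dataclasses.is_dataclass(row) else dict(row)
        missing = [c for c in schema if c not in d]
        if missing:
            raise ValueError(f"row is missing columns {missing}")
        dict_rows.append({c: d[c] for c in schema})
    df = pd.DataFrame(dict_rows, columns=list(schema))
    df.to_csv(path, sep="\t", index=False, float_format="%.3f")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


@dataclass(frozen=True)
class RunConfig:
    """All tunable thresholds of the pipeline, with their defaults.

    Defaults encode the study conditions: ESTs shorter than 100 nt or with
    more than 4% ambiguous bases are discarded, assembly merges overlaps
    with identity strictly above 0.80, homology hits tolerate at most 4
    mismatches, precursors are folded at 25 degC and must reach an MFEI
    magnitude of at least 0.6, and the miRNA:miRNA* duplex may contain at
    most 4 mismatches.
    """

    # -- EST cleaning ------------------------------------------------------
    min_est_len: int = 100            # nt; shorter post-mask ESTs discarded
    max_ambig_frac: float = 0.04      # strictly-greater fraction discards
    mask_min_match: int = 20          # nt; exact contaminant match to mask
    # -- assembly ----------------------------------------------------------
    overlap_identity: float = 0.80    # merge only if identity > this
    min_overlap_len: int = 40         # nt
    # -- homology scan -----------------------------------------------------
    max_mismatch_scan: int = 4
    max_bulges_scan: int = 3
    max_bulge_size_scan: int = 3      # nt per bulge
    exclusion_min_identity: float = 0.9
    exclusion_min_cov: float = 0.8
    # -- precursor folding / validation -----------------------------------
    fold_temperature: float = 25.0    # degC
    max_loop_size: int = 30           # nt, interior-loop cap of the engine
    mfei_threshold: float = 0.6       # applied to |MFEI|
    max_duplex_mismatch: int = 4
    max_flanked_bases: int = 4        # unpaired mature bases at duplex ends
                                      # (~2 nt overhang per end, as in Dicer
                                      # products)
    max_duplex_interruptions: int = 4  # helix breaks (loops/bulges) in the duplex
    precursor_max_window: int = 320   # nt, largest excised window
    precursor_window_step: int = 20   # nt
    # -- target rules ------------------------------------------------------
    max_target_mismatch: int = 4      # total cap over the site
    max_mismatch_pos1_9: int = 1
    max_consecutive_mismatch: int = 2
    wobble_weight: float = 1.0        # 1.0 = G:U counts as full mismatch
    # -- network -----------------------------------------------------------
    corr_threshold: float = 0.7       # Pearson r
    corr_mode: str = "signed"         # or "absolute"
    # -- reproducibility ---------------------------------------------------
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("max_ambig_frac", "overlap_identity", "exclusion_min_identity",
                     "exclusion_min_cov", "wobble_weight"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v!r}")
        for name in ("min_est_len", "mask_min_match", "min_overlap_len",
                     "max_mismatch_scan", "max_bulges_scan", "max_bulge_size_scan",
                     "max_loop_size", "max_duplex_mismatch", "max_flanked_bases",
                     "max_duplex_interruptions", "precursor_max_window",
                     "precursor_window_step", "max_target_mismatch",
                     "max_mismatch_pos1_9", "max_consecutive_mismatch"):
            v = getattr(self, name)
            if not (isinstance(v, int) and v >= 0):
                raise ConfigError(f"{name} must be a non-negative integer, got {v!r}")
        for name in ("mfei_threshold", "corr_threshold", "fold_temperature"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ConfigError(f"{name} must be finite, got {v!r}")
        if self.corr_mode not in ("signed", "absolute"):
            raise ConfigError(f"corr_mode must be 'signed' or 'absolute', got {self.corr_mode!r}")

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a flat YAML configuration file; absent file or ``None`` -> defaults.

    Unknown keys and out-of-range values are fatal and name the key.
    """
    if path is None:
        return RunConfig()
    path = Path(path)
    if not path.exists():
        return RunConfig()
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        return RunConfig()
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must contain a flat mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigError(f"unknown config keys: {unknown}")
    try:
        return RunConfig(**raw)
    except TypeError as exc:  # pragma: no cover - defensive
        raise ConfigError(str(exc)) from exc
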