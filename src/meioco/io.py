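"""Readers and writers for focus-map tables and result tables.

The interchange format is a delimited text table (CSV or TSV, autodetected
from the file extension) with one row per SC:

    genotype, nucleus_id, chromosome_id, sc_length_um, focus_positions

``focus_positions`` holds ";"-separated μm coordinates; an empty cell means
zero foci. All outputs are TSV with a fixed float format so identical inputs
produce byte-identical files.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import FocusTableError, FormatError, ValidationError
from .model import Cohort, SCObservation, build_cohorts

REQUIRED_COLUMNS = ("genotype", "nucleus_id", "chromosome_id", "sc_length_um", "focus_positions")
FOCUS_DELIMITER = ";"
_FLOAT_FORMAT = "%.6g"


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def read_focus_table(path: str | Path) -> dict[str, Cohort]:
    """Read a focus-map table into one :class:`Cohort` per genotype.

    Every row is validated against the SC invariants (positions within
    ``[0, length]``, strictly increasing, positive length). Validation is
    total: each malformed row yields exactly one diagnostic naming the row,
    and all diagnostics are raised together as :class:`FocusTableError`.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"focus table not found: {path}")
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}; "
                          f"found {list(df.columns)}")

    rows: list[tuple[str, SCObservation]] = []
    diagnostics: list[str] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        try:
            genotype = str(getattr(row, "genotype")).strip()
            nucleus_id = str(getattr(row, "nucleus_id")).strip()
            if not genotype or not nucleus_id:
                raise ValidationError("empty genotype or nucleus_id")
            try:
                chrom = int(str(getattr(row, "chromosome_id")).strip())
                length = float(str(getattr(row, "sc_length_um")).strip())
            except ValueError as exc:
                raise ValidationError(f"non-numeric field: {exc}") from None
            cell = str(getattr(row, "focus_positions")).strip()
            if cell:
                try:
                    positions = tuple(float(tok) for tok in cell.split(FOCUS_DELIMITER) if tok.strip())
                except ValueError:
                    raise ValidationError(f"non-numeric focus position in {cell!r}") from None
            else:
                positions = ()
            rows.append((genotype, SCObservation(nucleus_id, chrom, length, positions)))
        except ValidationError as exc:
            diagnostics.append(f"row {idx}: {exc}")
    if diagnostics:
        raise FocusTableError(diagnostics)
    return build_cohorts(rows)


def cohorts_to_table(cohorts: Mapping[str, Cohort] | Cohort) -> pd.DataFrame:
    """Flatten cohorts back into the interchange table (round-trip safe)."""
    if isinstance(cohorts, Cohort):
        cohorts = {cohorts.genotype: cohorts}
    records = []
    for cohort in cohorts.values():
        for nuc in cohort.nuclei:
            for sc in nuc.scs:
                records.append({
                    "genotype": cohort.genotype,
                    "nucleus_id": nuc.nucleus_id,
                    "chromosome_id": sc.chromosome_id,
                    "sc_length_um": sc.sc_length_um,
                    "focus_positions": FOCUS_DELIMITER.join(
                        repr(float(p)) for p in sc.focus_positions_um),
                })
    return pd.DataFrame.from_records(records, columns=list(REQUIRED_COLUMNS))


def write_focus_table(cohorts: Mapping[str, Cohort] | Cohort, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = cohorts_to_table(cohorts)
    # Shortest-repr floats: the written table round-trips to an identical
    # in-memory cohort and is still byte-stable for fixed input.
    df.to_csv(path, sep=_sep_for(path), index=False, lineterminator="\n")
    return path


def write_results(tables: Mapping[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write result tables as TSV, one file per table name.

    Output is byte-stable for a fixed input: fixed float format, ``\\n`` line
    endings, no index column. An empty table yields a header-only file.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        path = out_dir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT, lineterminator="\n")
        written.append(path)
    return written


def write_manifest(path: str | Path, entries: Mapping[str, object]) -> Path:
    """Write a flat key-value run manifest (``key = value`` per line)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"{k} = {v}" for k, v in entries.items()]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def config_hash(entries: Mapping[str, object]) -> str:
    """Short stable hash of a parameter mapping, for provenance manifests."""
    blob = "\n".join(f"{k}={v}" for k, v in
                     sorted(entries.items(), key=lambda kv: str(kv[0]))).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
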