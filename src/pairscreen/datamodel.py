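"""Core data types and delimited-table I/O for single-dose combination screens.

The unit of data is a viability measurement: the surviving fraction ``g`` of
cells (relative to untreated control) after treatment with a *cocktail* — a set
of one or more drugs, each at one fixed dose.  A screen is a collection of such
measurements for one or more cell lines, ideally fully factorial (every subset
of a drug panel measured).

This module defines

* :class:`Cocktail` — a canonicalized, order-free drug set;
* :class:`ViabilityRecord` — one measurement (mean, standard error, optional
  per-repeat values, optional interaction score with bootstrap CI bounds);
* :class:`CombinationDataset` — a validated keyed collection of records;
* :func:`read_dataset` / :func:`write_dataset` — delimited text round trip;
* :func:`table2_fixture` — the embedded reference screen of all combinations
  of six chemotherapy drugs (CPT, CisPt, CbPt, NCZ, MG132, Etopo) on the
  H1299 and HeLa cell lines.
"""

from __future__ import annotations

import csv
import io
import logging
import math
from dataclasses import dataclass, field, replace
from itertools import combinations
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from .exceptions import ParseError, ValidationError

logger = logging.getLogger("pairscreen")

#: Viabilities slightly above 1 are legitimate measurement noise; values beyond
#: this cap almost certainly indicate a unit error (e.g. percent instead of
#: fraction) and are rejected.
VIABILITY_CAP = 2.0

#: Marker understood as "missing value" in input tables (alongside empty cells).
MISSING_MARKERS = {"", "-", "−", "na", "nan", "none"}


# ---------------------------------------------------------------------------
# Cocktail
# ---------------------------------------------------------------------------


def canonical_drugs(drugs: Iterable[str]) -> tuple[str, ...]:
    """Canonicalize drug identifiers: strip, uppercase, sort; reject duplicates."""
    tokens = [str(d).strip().upper() for d in drugs]
    if any(not t for t in tokens):
        raise ValidationError(f"empty drug identifier in {list(drugs)!r}")
    out = tuple(sorted(tokens))
    if len(set(out)) != len(out):
        dupes = sorted({t for t in out if out.count(t) > 1})
        raise ValidationError(f"duplicate drug identifier(s): {', '.join(dupes)}")
    return out


@dataclass(frozen=True, order=True)
class Cocktail:
    """A canonical set of drug identifiers.

    Two cocktails with the same drug set compare equal regardless of input
    order; the canonical string form joins the sorted identifiers with ``+``.
    """

    drugs: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "drugs", canonical_drugs(self.drugs))

    @classmethod
    def parse(cls, name: str) -> "Cocktail":
        """Build a cocktail from a ``+``-joined string such as ``"CPT+CisPt"``."""
        return cls(tuple(name.split("+")))

    @property
    def order(self) -> int:
        """Number of drugs M in the cocktail."""
        return len(self.drugs)

    @property
    def name(self) -> str:
        return "+".join(self.drugs)

    def subsets(self, k: int) -> list["Cocktail"]:
        """All sub-cocktails of ``k`` drugs, in canonical order."""
        return [Cocktail(c) for c in combinations(self.drugs, k)]

    def pairs(self) -> list["Cocktail"]:
        """The M(M-1)/2 constituent drug pairs."""
        return self.subsets(2)

    def __contains__(self, drug: str) -> bool:
        return drug.strip().upper() in self.drugs

    def __str__(self) -> str:
        return self.name


# ---------------------------------------------------------------------------
# ViabilityRecord
# ---------------------------------------------------------------------------


@dataclass
class ViabilityRecord:
    """One measured (cell line, cocktail) viability.

    ``interaction``/``ci_low``/``ci_high`` optionally carry a Bliss-deviation
    interaction score I (natural-log units) with its 5th/95th bootstrap
    percentile bounds, as published tables often print them next to the means.
    ``ste`` consistency with ``repeats`` is deliberately not enforced: a
    published standard error may come from a different aggregation than the
    per-repeat values at hand.
    """

    cell_line: str
    cocktail: Cocktail
    viability: float
    ste: float | None = None
    repeats: tuple[float, ...] | None = None
    interaction: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None

    def __post_init__(self) -> None:
        self.cell_line = str(self.cell_line).strip()
        if not self.cell_line:
            raise ValidationError("cell_line must be a non-empty string")
        v = float(self.viability)
        if not math.isfinite(v) or v < 0:
            raise ValidationError(
                f"{self.cell_line} {self.cocktail}: viability must be finite and >= 0, got {v!r}"
            )
        if v > VIABILITY_CAP:
            raise ValidationError(
                f"{self.cell_line} {self.cocktail}: viability {v} exceeds cap "
                f"{VIABILITY_CAP} (percent instead of fraction?)"
            )
        self.viability = v
        if self.ste is not None:
            s = float(self.ste)
            if not math.isfinite(s) or s < 0:
                raise ValidationError(
                    f"{self.cell_line} {self.cocktail}: ste must be finite and >= 0"
                )
            self.ste = s
        if self.repeats is not None:
            reps = tuple(float(r) for r in self.repeats)
            if len(reps) < 1:
                raise ValidationError("repeats, if present, must contain at least one value")
            if any((not math.isfinite(r)) or r < 0 for r in reps):
                raise ValidationError(
                    f"{self.cell_line} {self.cocktail}: repeats must be finite and >= 0"
                )
            self.repeats = reps
        if (self.ci_low is None) != (self.ci_high is None):
            raise ValidationError("ci_low and ci_high must be given together")
        if self.ci_low is not None and float(self.ci_low) > float(self.ci_high):
            raise ValidationError(
                f"{self.cell_line} {self.cocktail}: ci_low > ci_high"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.cell_line, self.cocktail.name)

    @property
    def order(self) -> int:
        return self.cocktail.order


# ---------------------------------------------------------------------------
# CombinationDataset
# ---------------------------------------------------------------------------


@dataclass
class CombinationDataset:
    """A keyed, validated collection of viability records.

    Keys are ``(cell_line, canonical cocktail name)`` and unique.  Validation
    enforces that every drug appearing in a multi-drug cocktail has the
    corresponding single-drug record for that cell line.  Missing pairs are
    permitted (fully factorial designs lose rows in practice) and discoverable
    via :meth:`missing_pairs`.
    """

    name: str = ""
    records: dict[tuple[str, str], ViabilityRecord] = field(default_factory=dict)

    def add(self, record: ViabilityRecord) -> None:
        if record.key in self.records:
            raise ValidationError(f"duplicate record for {record.key}")
        self.records[record.key] = record

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ViabilityRecord]:
        return iter(self.records.values())

    def get(self, cell_line: str, cocktail: Cocktail | str) -> ViabilityRecord | None:
        name = cocktail.name if isinstance(cocktail, Cocktail) else Cocktail.parse(cocktail).name
        return self.records.get((cell_line, name))

    def cell_lines(self) -> list[str]:
        return sorted({r.cell_line for r in self})

    def cocktails(self, cell_line: str | None = None) -> list[Cocktail]:
        """Distinct cocktails (union over cell lines unless one is given)."""
        seen = {
            r.cocktail
            for r in self
            if cell_line is None or r.cell_line == cell_line
        }
        return sorted(seen, key=lambda c: (c.order, c.name))

    def drugs(self, cell_line: str | None = None) -> list[str]:
        out: set[str] = set()
        for r in self:
            if cell_line is None or r.cell_line == cell_line:
                out.update(r.cocktail.drugs)
        return sorted(out)

    def singles_map(self, cell_line: str) -> dict[str, float]:
        """Map drug -> single-drug viability for one cell line."""
        return {
            r.cocktail.drugs[0]: r.viability
            for r in self
            if r.cell_line == cell_line and r.order == 1
        }

    def pairs_map(self, cell_line: str) -> dict[Cocktail, float]:
        """Map pair cocktail -> viability for one cell line."""
        return {
            r.cocktail: r.viability
            for r in self
            if r.cell_line == cell_line and r.order == 2
        }

    def missing_pairs(self, cell_line: str) -> list[Cocktail]:
        """Pairs of the cell line's single-drug panel with no measured record."""
        singles = sorted(self.singles_map(cell_line))
        have = {c.name for c in self.pairs_map(cell_line)}
        return [
            Cocktail(p) for p in combinations(singles, 2)
            if "+".join(p) not in have
        ]

    def subset(self, cell_line: str) -> "CombinationDataset":
        out = CombinationDataset(name=f"{self.name}[{cell_line}]")
        for r in self:
            if r.cell_line == cell_line:
                out.add(replace(r))
        return out

    def validate(self) -> None:
        """Check single-drug coverage for every multi-drug cocktail."""
        offenders: list[str] = []
        singles_by_line = {cl: set(self.singles_map(cl)) for cl in self.cell_lines()}
        for r in self:
            if r.order < 2:
                continue
            absent = [d for d in r.cocktail.drugs if d not in singles_by_line[r.cell_line]]
            if absent:
                offenders.append(f"{r.cell_line} {r.cocktail.name}: no single(s) {'+'.join(absent)}")
        if offenders:
            raise ValidationError(
                "missing single-drug records:\n  " + "\n  ".join(sorted(offenders))
            )


# ---------------------------------------------------------------------------
# Delimited-table I/O
# ---------------------------------------------------------------------------

_BASE_COLUMNS = ("cell_line", "drugs", "viability")
_OPT_COLUMNS = ("ste", "interaction", "ci_low", "ci_high")


def _is_missing(cell: str | None) -> bool:
    return cell is None or cell.strip().lower() in MISSING_MARKERS


def _parse_float(cell: str, column: str, row_no: int) -> float:
    # Published tables use U+2212 for the minus sign.
    text = cell.strip().replace("−", "-")
    try:
        return float(text)
    except ValueError:
        raise ParseError(f"row {row_no}: malformed number {cell!r} in column {column!r}") from None


def _sniff_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return "\t" if "\t" in sample else ","


def read_dataset(
    path: str | Path,
    delimiter: str | None = None,
    name: str | None = None,
    validate: bool = True,
) -> CombinationDataset:
    """Read a delimited viability table into a :class:`CombinationDataset`.

    Requires columns ``cell_line``, ``drugs``, ``viability``; accepts optional
    ``ste``, ``interaction``, ``ci_low``, ``ci_high`` and repeats either wide
    (``repeat_1..repeat_n``) or long (``repeat_index``, ``repeat_value``).
    The delimiter (comma or tab) is autodetected unless given.  Lines starting
    with ``#`` are treated as comments.  Rows whose viability cell is blank or
    ``-`` are skipped with a logged warning.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    return _read_dataset_text(text, delimiter=delimiter, name=name or path.stem, validate=validate)


def _read_dataset_text(
    text: str,
    delimiter: str | None = None,
    name: str = "",
    validate: bool = True,
) -> CombinationDataset:
    lines = [ln for ln in text.splitlines() if not ln.startswith("#")]
    if not lines or not lines[0].strip():
        raise ParseError("empty input: missing header row")
    if delimiter is None:
        delimiter = _sniff_delimiter(lines[0])
    reader = csv.DictReader(io.StringIO("\n".join(lines)), delimiter=delimiter)
    header = [h.strip() for h in (reader.fieldnames or [])]
    missing_cols = [c for c in _BASE_COLUMNS if c not in header]
    if missing_cols:
        raise ParseError(f"missing required column(s): {', '.join(missing_cols)}")

    wide_repeat_cols = sorted(
        (h for h in header if h.startswith("repeat_") and h[7:].isdigit()),
        key=lambda h: int(h[7:]),
    )
    long_format = "repeat_index" in header and "repeat_value" in header

    dataset = CombinationDataset(name=name)
    # long-format rows are accumulated per key, then finalized
    long_rows: dict[tuple[str, str], ViabilityRecord] = {}
    long_repeats: dict[tuple[str, str], list[tuple[int, float]]] = {}

    for row_no, row in enumerate(reader, start=2):
        cell_line = (row.get("cell_line") or "").strip()
        drugs_cell = (row.get("drugs") or "").strip()
        if not cell_line and not drugs_cell:
            continue
        cocktail = Cocktail.parse(drugs_cell)
        if _is_missing(row.get("viability")):
            logger.warning(
                "row %d: %s %s has no viability value; record skipped",
                row_no, cell_line, cocktail.name,
            )
            continue
        viability = _parse_float(row["viability"], "viability", row_no)
        optional: dict[str, float | None] = {}
        for col in _OPT_COLUMNS:
            cell = row.get(col)
            optional[col] = None if _is_missing(cell) else _parse_float(cell, col, row_no)

        repeats: tuple[float, ...] | None = None
        if wide_repeat_cols:
            vals = [
                _parse_float(row[c], c, row_no)
                for c in wide_repeat_cols
                if not _is_missing(row.get(c))
            ]
            repeats = tuple(vals) if vals else None

        record = ViabilityRecord(
            cell_line=cell_line,
            cocktail=cocktail,
            viability=viability,
            ste=optional["ste"],
            repeats=repeats,
            interaction=optional["interaction"],
            ci_low=optional["ci_low"],
            ci_high=optional["ci_high"],
        )

        if long_format and not _is_missing(row.get("repeat_index")):
            idx = int(_parse_float(row["repeat_index"], "repeat_index", row_no))
            val = _parse_float(row["repeat_value"], "repeat_value", row_no)
            key = record.key
            bucket = long_repeats.setdefault(key, [])
            if any(i == idx for i, _ in bucket):
                raise ValidationError(
                    f"row {row_no}: duplicate repeat_index {idx} for {key}"
                )
            bucket.append((idx, val))
            long_rows.setdefault(key, record)
        else:
            dataset.add(record)

    for key, record in long_rows.items():
        reps = tuple(v for _, v in sorted(long_repeats[key]))
        dataset.add(replace(record, repeats=reps))

    if validate:
        dataset.validate()
    return dataset


def write_dataset(dataset: CombinationDataset, path: str | Path, delimiter: str = ",") -> None:
    """Write a dataset as delimited text; :func:`read_dataset` round-trips it.

    Numbers are written with 12 significant digits so the round trip preserves
    values to floating-point text precision.
    """
    path = Path(path)
    n_rep = max((len(r.repeats) for r in dataset if r.repeats), default=0)
    header = list(_BASE_COLUMNS) + list(_OPT_COLUMNS) + [f"repeat_{i + 1}" for i in range(n_rep)]

    def fmt(x: float | None) -> str:
        return "" if x is None else format(float(x), ".12g")

    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(header)
        for record in sorted(dataset, key=lambda r: (r.cell_line, r.order, r.cocktail.name)):
            reps = list(record.repeats) if record.repeats else []
            writer.writerow(
                [record.cell_line, record.cocktail.name, fmt(record.viability),
                 fmt(record.ste), fmt(record.interaction), fmt(record.ci_low),
                 fmt(record.ci_high)]
                + [fmt(v) for v in reps]
                + [""] * (n_rep - len(reps))
            )


# ---------------------------------------------------------------------------
# Embedded reference screen (fully factorial, 6 drugs x 2 cell lines)
# ---------------------------------------------------------------------------

# Published measurements for every combination of the six-drug panel
# {CPT, CisPt, CbPt, NCZ, MG132, Etopo} at fixed LD20 doses on H1299 and HeLa
# cells: mean viability, standard error, interaction score
# I = ln(1 + g - Bliss product) and its 5%/95% bootstrap CI.  "-" marks the
# HeLa combinations excluded for large between-repeat variation.  Singles have
# no interaction columns by construction (I is a deviation from Bliss).
_TABLE2_TSV = """\
drugs	h1299_viability	h1299_ste	h1299_interaction	h1299_ci_low	h1299_ci_high	hela_viability	hela_ste	hela_interaction	hela_ci_low	hela_ci_high
CPT	0.77	0.01	-	-	-	0.73	0.02	-	-	-
CisPt	0.82	0.01	-	-	-	0.65	0.03	-	-	-
CbPt	0.77	0.01	-	-	-	0.27	0.04	-	-	-
NCZ	0.73	0.02	-	-	-	0.83	0.02	-	-	-
MG132	0.68	0.02	-	-	-	0.70	0.02	-	-	-
Etopo	0.72	0.01	-	-	-	0.71	0.02	-	-	-
CPT+CisPt	0.67	0.02	0.04	0.01	0.08	0.62	0.02	0.13	0.10	0.16
CPT+CbPt	0.58	0.02	-0.01	-0.05	0.02	0.09	0.01	-0.14	-0.19	-0.09
CPT+NCZ	0.66	0.02	0.07	0.04	0.09	0.66	0.03	0.10	0.07	0.13
CPT+MG132	0.66	0.01	0.12	0.09	0.15	0.76	0.02	0.21	0.17	0.24
CPT+Etopo	0.51	0.01	-0.05	-0.08	-0.02	0.60	0.02	0.07	0.04	0.10
CisPt+CbPt	0.73	0.02	0.08	0.05	0.11	0.11	0.02	-0.07	-0.09	-0.05
CisPt+NCZ	0.72	0.02	0.10	0.07	0.12	0.87	0.04	0.24	0.19	0.29
CisPt+MG132	0.74	0.02	0.15	0.12	0.18	0.80	0.03	0.28	0.24	0.32
CisPt+Etopo	0.68	0.02	0.08	0.06	0.11	0.63	0.01	0.15	0.11	0.18
CbPt+NCZ	0.41	0.02	-0.17	-0.23	-0.11	-	-	-	-	-
CbPt+MG132	0.58	0.02	0.06	0.03	0.09	0.25	0.03	0.05	0.03	0.07
CbPt+Etopo	0.64	0.02	0.08	0.06	0.11	0.17	0.01	-0.02	-0.06	0.01
NCZ+MG132	0.47	0.02	-0.04	-0.08	-0.01	0.78	0.02	0.15	0.11	0.19
NCZ+Etopo	0.78	0.02	0.23	0.20	0.25	0.77	0.03	0.18	0.13	0.22
MG132+Etopo	0.72	0.02	0.21	0.18	0.24	0.83	0.02	0.28	0.23	0.32
CPT+CisPt+CbPt	0.37	0.04	-0.07	-0.13	-0.01	0.08	0.00	-0.07	-0.10	-0.04
CPT+CisPt+NCZ	0.31	0.03	-0.16	-0.26	-0.07	0.60	0.02	0.19	0.13	0.23
CPT+CisPt+MG132	0.37	0.01	-0.04	-0.10	0.02	0.55	0.01	0.18	0.14	0.22
CPT+CisPt+Etopo	0.40	0.04	-0.03	-0.12	0.07	0.41	0.01	0.06	0.03	0.09
CPT+CbPt+NCZ	0.53	0.01	0.05	-0.01	0.12	-	-	-	-	-
CPT+CbPt+MG132	0.31	0.02	-0.06	-0.13	0.00	0.08	0.04	-0.07	-0.09	-0.05
CPT+CbPt+Etopo	0.32	0.03	-0.08	-0.20	0.04	0.02	0.00	-0.14	-0.19	-0.10
CPT+NCZ+MG132	0.28	0.05	-0.11	-0.18	-0.05	0.63	0.02	0.19	0.17	0.22
CPT+NCZ+Etopo	0.34	0.00	-0.08	-0.14	-0.02	0.54	0.00	0.14	0.10	0.19
CPT+MG132+Etopo	0.58	0.03	0.14	0.05	0.25	0.64	0.01	0.22	0.16	0.27
CisPt+CbPt+NCZ	0.18	0.01	-0.35	-0.45	-0.26	-	-	-	-	-
CisPt+CbPt+MG132	0.55	0.01	0.08	-0.02	0.17	0.10	0.00	-0.04	-0.06	-0.01
CisPt+CbPt+Etopo	0.52	0.02	0.02	-0.03	0.07	0.07	0.01	-0.07	-0.09	-0.04
CisPt+NCZ+MG132	0.22	0.01	-0.25	-0.42	-0.10	0.74	0.02	0.26	0.23	0.30
CisPt+NCZ+Etopo	0.68	0.01	0.20	0.15	0.25	0.64	0.01	0.20	0.17	0.24
CisPt+MG132+Etopo	0.72	0.01	0.26	0.21	0.31	0.61	0.01	0.24	0.21	0.27
CbPt+NCZ+MG132	0.15	0.01	-0.30	-0.51	-0.14	-	-	-	-	-
CbPt+NCZ+Etopo	0.29	0.01	-0.05	-0.12	0.02	-	-	-	-	-
CbPt+MG132+Etopo	0.50	0.01	0.17	0.12	0.23	0.19	0.00	0.05	0.02	0.07
NCZ+MG132+Etopo	0.30	0.01	0.02	-0.01	0.05	0.71	0.02	0.25	0.20	0.30
CPT+CisPt+CbPt+NCZ	0.14	0.00	-0.15	-0.21	-0.10	-	-	-	-	-
CPT+CisPt+CbPt+MG132	0.19	0.01	-0.07	-0.14	0.00	0.03	0.00	-0.09	-0.13	-0.05
CPT+CisPt+CbPt+Etopo	0.10	0.02	-0.22	-0.28	-0.15	0.02	0.00	-0.09	-0.11	-0.06
CPT+CisPt+NCZ+MG132	0.17	0.01	-0.06	-0.11	-0.01	0.48	0.02	0.17	0.14	0.20
CPT+CisPt+NCZ+Etopo	0.15	0.01	-0.13	-0.17	-0.09	0.41	0.01	0.12	0.09	0.16
CPT+CisPt+MG132+Etopo	0.16	0.01	-0.09	-0.15	-0.02	-	-	-	-	-
CPT+CbPt+NCZ+MG132	0.16	0.00	-0.14	-0.23	-0.07	-	-	-	-	-
CPT+CbPt+NCZ+Etopo	0.14	0.01	-0.22	-0.28	-0.15	-	-	-	-	-
CPT+CbPt+MG132+Etopo	0.25	0.01	-0.03	-0.09	0.03	0.03	0.00	-0.06	-0.09	-0.03
CPT+NCZ+MG132+Etopo	0.21	0.01	-0.08	-0.12	-0.04	0.77	0.02	0.40	0.37	0.42
CisPt+CbPt+NCZ+MG132	0.10	0.00	-0.24	-0.32	-0.16	-	-	-	-	-
CisPt+CbPt+NCZ+Etopo	0.21	0.01	-0.10	-0.17	-0.03	-	-	-	-	-
CisPt+CbPt+MG132+Etopo	0.55	0.01	0.22	0.19	0.26	0.04	0.01	-0.06	-0.09	-0.04
CisPt+NCZ+MG132+Etopo	0.37	0.01	0.08	0.03	0.13	0.80	0.01	0.40	0.37	0.43
CbPt+NCZ+MG132+Etopo	0.11	0.01	-0.20	-0.25	-0.14	-	-	-	-	-
CPT+CisPt+CbPt+NCZ+MG132	0.22	0.04	-0.19	-0.27	-0.11	-	-	-	-	-
CPT+CisPt+CbPt+NCZ+Etopo	0.27	0.02	0.00	-0.06	0.05	-	-	-	-	-
CPT+CisPt+CbPt+MG132+Etopo	0.43	0.01	0.06	0.00	0.13	0.00	0.00	-0.06	-0.08	-0.04
CPT+CisPt+NCZ+MG132+Etopo	0.26	0.01	0.01	-0.06	0.08	0.58	0.01	0.32	0.30	0.34
CPT+CbPt+NCZ+MG132+Etopo	0.17	0.03	-0.15	-0.25	-0.06	-	-	-	-	-
CisPt+CbPt+NCZ+MG132+Etopo	0.20	0.01	-0.09	-0.14	-0.03	-	-	-	-	-
CPT+CisPt+CbPt+NCZ+MG132+Etopo	0.29	0.03	0.04	-0.01	0.09	-	-	-	-	-
"""

_CELL_LINES = (("H1299", "h1299"), ("HeLa", "hela"))


def table2_fixture() -> CombinationDataset:
    """The embedded two-cell-line reference screen.

    Returns all 63 H1299 records (6 singles, 15 pairs, 20 triplets,
    15 quadruplets, 6 quintuplets, 1 sextuplet) and the 46 HeLa records with
    published values; the 17 HeLa combinations excluded for large
    between-repeat variation are absent and discoverable via
    :meth:`CombinationDataset.missing_pairs` and dataset queries.
    """
    dataset = CombinationDataset(name="table2")
    reader = csv.DictReader(io.StringIO(_TABLE2_TSV), delimiter="\t")
    for row in reader:
        cocktail = Cocktail.parse(row["drugs"])
        for cell_line, prefix in _CELL_LINES:
            if _is_missing(row[f"{prefix}_viability"]):
                continue
            dataset.add(
                ViabilityRecord(
                    cell_line=cell_line,
                    cocktail=cocktail,
                    viability=float(row[f"{prefix}_viability"]),
                    ste=float(row[f"{prefix}_ste"]),
                    interaction=None
                    if _is_missing(row[f"{prefix}_interaction"])
                    else float(row[f"{prefix}_interaction"]),
                    ci_low=None
                    if _is_missing(row[f"{prefix}_ci_low"])
                    else float(row[f"{prefix}_ci_low"]),
                    ci_high=None
                    if _is_missing(row[f"{prefix}_ci_high"])
                    else float(row[f"{prefix}_ci_high"]),
                )
            )
    dataset.validate()
    return dataset
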