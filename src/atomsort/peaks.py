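"""Peak lists and reference-compound databases for ¹H–¹³C HSQC spectra.

An HSQC spectrum reduces, for matching purposes, to a list of (δ¹H, δ¹³C)
correlations in ppm, optionally with an intensity.  Reference compounds are
named peak lists with an optional molecular formula and molecular weight.
Two plain-text formats are supported: a csv dialect with header
``h_ppm,c_ppm[,intensity]`` and Sparky-style ``.list`` exports
(whitespace-delimited ``assignment w1 w2`` lines with w1 = ¹³C, w2 = ¹H).
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "Peak2D",
    "PeakList",
    "ReferenceCompound",
    "ReferenceDatabase",
    "PeakListParseError",
    "read_peak_list",
    "write_peak_list",
    "read_reference_database",
    "write_reference_database",
    "build_reference_from_assignments",
    "merge_close_peaks",
    "DEFAULT_MERGE_TOL_H",
    "DEFAULT_MERGE_TOL_C",
]

# ~digital resolution of a routine HSQC, used when collapsing near-degenerate
# correlations (e.g. overlapping methyls) into one peak
DEFAULT_MERGE_TOL_H = 0.03
DEFAULT_MERGE_TOL_C = 0.3


class PeakListParseError(ValueError):
    """A peak-list file could not be parsed (message names the line)."""


@dataclass(frozen=True)
class Peak2D:
    """One ¹H–¹³C correlation: proton and carbon chemical shifts in ppm."""

    h_shift: float
    c_shift: float
    intensity: float | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.h_shift) and math.isfinite(self.c_shift)):
            raise ValueError("chemical shifts must be finite")
        if self.intensity is not None:
            if not math.isfinite(self.intensity) or self.intensity < 0:
                raise ValueError("intensity must be finite and >= 0")


class PeakList:
    """Ordered collection of :class:`Peak2D`.

    Order is stable under read/write round-trips and duplicate coordinates
    are allowed; merging near-coincident peaks is always an explicit
    operation (:func:`merge_close_peaks`), never implicit.
    """

    def __init__(self, peaks: Iterable[Peak2D] = (), label: str = "") -> None:
        self.peaks: list[Peak2D] = list(peaks)
        self.label = label

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak2D]:
        return iter(self.peaks)

    def __getitem__(self, i: int) -> Peak2D:
        return self.peaks[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeakList):
            return NotImplemented
        return self.peaks == other.peaks and self.label == other.label

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PeakList({len(self.peaks)} peaks, label={self.label!r})"

    def h_shifts(self) -> list[float]:
        return [p.h_shift for p in self.peaks]

    def c_shifts(self) -> list[float]:
        return [p.c_shift for p in self.peaks]


@dataclass
class ReferenceCompound:
    """A named reference compound: peak list plus formula / MW metadata.

    If both ``formula`` and ``mol_weight`` are given, the average mass
    computed from the formula must agree with ``mol_weight`` within 0.5%.
    """

    name: str
    peaks: PeakList
    formula: str | None = None
    mol_weight: float | None = None

    def __post_init__(self) -> None:
        if len(self.peaks) == 0:
            raise ValueError(f"reference compound {self.name!r} has no peaks")
        if self.formula is not None and self.mol_weight is not None:
            from .masses import average_mass, parse_formula

            calc = average_mass(parse_formula(self.formula))
            if abs(calc - self.mol_weight) > 0.005 * self.mol_weight:
                raise ValueError(
                    f"{self.name!r}: average mass from formula {self.formula} "
                    f"({calc:.2f}) disagrees with mol_weight {self.mol_weight} "
                    "by more than 0.5%"
                )

    def resolve_mol_weight(self) -> float:
        """Molecular weight, falling back to the formula's average mass."""
        if self.mol_weight is not None:
            return self.mol_weight
        if self.formula is not None:
            from .masses import average_mass, parse_formula

            return average_mass(parse_formula(self.formula))
        raise ValueError(f"{self.name!r} has neither mol_weight nor formula")


class ReferenceDatabase:
    """Reference compounds keyed by unique name."""

    def __init__(self, compounds: Iterable[ReferenceCompound]) -> None:
        self.compounds: dict[str, ReferenceCompound] = {}
        for c in compounds:
            if c.name in self.compounds:
                raise ValueError(f"duplicate compound name {c.name!r}")
            self.compounds[c.name] = c
        if not self.compounds:
            raise ValueError("reference database must be nonempty")

    def __len__(self) -> int:
        return len(self.compounds)

    def __iter__(self) -> Iterator[ReferenceCompound]:
        return iter(self.compounds.values())

    def __contains__(self, name: str) -> bool:
        return name in self.compounds

    def __getitem__(self, name: str) -> ReferenceCompound:
        return self.compounds[name]

    def names(self) -> list[str]:
        return list(self.compounds)


def _parse_float(token: str, path: os.PathLike | str, lineno: int) -> float:
    try:
        v = float(token)
    except ValueError:
        raise PeakListParseError(
            f"{path}: malformed numeric field {token!r} at line {lineno}"
        ) from None
    if not math.isfinite(v):
        raise PeakListParseError(f"{path}: non-finite value at line {lineno}")
    return v


def read_peak_list(path: os.PathLike | str, dialect: str = "csv") -> PeakList:
    """Read a peak list from ``path``.

    ``dialect='csv'`` expects a header ``h_ppm,c_ppm[,intensity]``;
    ``dialect='sparky'`` expects whitespace-delimited lines of
    ``assignment  w1  w2  [intensity]`` where w1 is the ¹³C shift and w2 the
    ¹H shift.  Blank lines and lines starting with ``#`` are skipped.
    Raises :class:`PeakListParseError` on malformed fields (naming the line)
    or if no peaks are found.
    """
    path = Path(path)
    if dialect not in ("csv", "sparky"):
        raise ValueError(f"unknown dialect {dialect!r}")
    peaks: list[Peak2D] = []
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()

    if dialect == "csv":
        header_seen = False
        for lineno, raw in enumerate(lines, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = [f.strip() for f in line.split(",")]
            if not header_seen:
                if fields[0].lower() != "h_ppm":
                    raise PeakListParseError(
                        f"{path}: expected header starting with 'h_ppm' at line {lineno}"
                    )
                header_seen = True
                continue
            if len(fields) < 2:
                raise PeakListParseError(f"{path}: too few fields at line {lineno}")
            h = _parse_float(fields[0], path, lineno)
            c = _parse_float(fields[1], path, lineno)
            inten = None
            if len(fields) >= 3 and fields[2] != "":
                inten = _parse_float(fields[2], path, lineno)
            peaks.append(Peak2D(h, c, inten))
    else:  # sparky
        for lineno, raw in enumerate(lines, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if fields[0].lower() == "assignment":  # Sparky header line
                continue
            if len(fields) < 3:
                raise PeakListParseError(f"{path}: too few fields at line {lineno}")
            c = _parse_float(fields[1], path, lineno)  # w1 = 13C
            h = _parse_float(fields[2], path, lineno)  # w2 = 1H
            inten = _parse_float(fields[3], path, lineno) if len(fields) >= 4 else None
            peaks.append(Peak2D(h, c, inten))

    if not peaks:
        raise PeakListParseError(f"{path}: no peaks found")
    return PeakList(peaks, label=path.stem)


def write_peak_list(peaks: PeakList, path: os.PathLike | str) -> None:
    """Write ``peaks`` as csv (``h_ppm,c_ppm[,intensity]``, 4 decimals)."""
    path = Path(path)
    has_intensity = any(p.intensity is not None for p in peaks)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("h_ppm,c_ppm,intensity\n" if has_intensity else "h_ppm,c_ppm\n")
        for p in peaks:
            row = f"{p.h_shift:.4f},{p.c_shift:.4f}"
            if has_intensity:
                row += f",{p.intensity:.4f}" if p.intensity is not None else ","
            fh.write(row + "\n")


def read_reference_database(path: os.PathLike | str) -> ReferenceDatabase:
    """Load a reference database from a directory (or its manifest file).

    The directory holds one peak-list file per compound plus ``manifest.tsv``
    with columns ``name, formula, mol_weight, file`` (empty formula/MW
    allowed).  A manifest row naming a missing file is an error, as are
    duplicate compound names.
    """
    path = Path(path)
    manifest = path / "manifest.tsv" if path.is_dir() else path
    base = manifest.parent
    if not manifest.exists():
        raise FileNotFoundError(f"manifest not found: {manifest}")

    compounds: list[ReferenceCompound] = []
    with open(manifest, encoding="utf-8") as fh:
        header = fh.readline().strip().split("\t")
        idx = {col: i for i, col in enumerate(header)}
        for col in ("name", "formula", "mol_weight", "file"):
            if col not in idx:
                raise ValueError(f"{manifest}: missing manifest column {col!r}")
        for raw in fh:
            if not raw.strip() or raw.startswith("#"):
                continue
            fields = raw.rstrip("\n").split("\t")
            name = fields[idx["name"]].strip()
            formula = fields[idx["formula"]].strip() or None
            mw_text = fields[idx["mol_weight"]].strip()
            mol_weight = float(mw_text) if mw_text else None
            fname = fields[idx["file"]].strip()
            fpath = base / fname
            if not fpath.exists():
                raise FileNotFoundError(
                    f"{manifest}: compound {name!r} references missing file {fname}"
                )
            dialect = "sparky" if fname.endswith(".list") else "csv"
            peaks = read_peak_list(fpath, dialect=dialect)
            compounds.append(ReferenceCompound(name, peaks, formula, mol_weight))
    return ReferenceDatabase(compounds)


def write_reference_database(db: ReferenceDatabase, path: os.PathLike | str) -> None:
    """Write ``db`` as a directory of csv peak lists plus manifest.tsv."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "manifest.tsv", "w", encoding="utf-8") as fh:
        fh.write("name\tformula\tmol_weight\tfile\n")
        for i, comp in enumerate(db):
            fname = f"compound_{i:03d}.csv"
            write_peak_list(comp.peaks, path / fname)
            mw = "" if comp.mol_weight is None else f"{comp.mol_weight:g}"
            fh.write(f"{comp.name}\t{comp.formula or ''}\t{mw}\t{fname}\n")


def _strip_pair_suffix(label: str) -> str:
    return label[:-1] if label and label[-1] in "ab" else label


def build_reference_from_assignments(
    assignments: Sequence[Mapping[str, object]] | "object",
    merge_tol_h: float = DEFAULT_MERGE_TOL_H,
    merge_tol_c: float = DEFAULT_MERGE_TOL_C,
    *,
    name: str = "",
    formula: str | None = None,
    mol_weight: float | None = None,
    skip_missing_carbon: bool = False,
) -> ReferenceCompound:
    """Build a reference compound from tabulated NMR assignments.

    ``assignments`` is a sequence of mappings (or a DataFrame) with keys
    ``position`` (label), ``h_shift`` (required) and ``c_shift`` (may be
    None).  Diastereotopic partners that share a carbon are tabulated with
    the carbon on one row only; a row lacking its own ¹³C inherits the
    carbon of its partner row (same position label up to a trailing a/b).
    N–H rows carry no carbon and must be excluded by the caller (HSQC here
    is ¹H–¹³C).  A row with neither its own nor an inheritable carbon raises
    (listing the position labels) unless ``skip_missing_carbon`` is set.
    Peaks closer than (merge_tol_h, merge_tol_c) in both dimensions are then
    merged to their centroid.
    """
    if hasattr(assignments, "to_dict"):  # DataFrame
        assignments = assignments.to_dict("records")
    rows = list(assignments)
    if not rows:
        raise ValueError("empty assignment table")

    # carbon available per pair group
    group_carbon: dict[str, float] = {}
    for row in rows:
        c = row.get("c_shift")
        if c is not None and not (isinstance(c, float) and math.isnan(c)):
            group_carbon.setdefault(_strip_pair_suffix(str(row["position"])), float(c))

    peaks: list[Peak2D] = []
    missing: list[str] = []
    for row in rows:
        label = str(row["position"])
        h = float(row["h_shift"])
        c = row.get("c_shift")
        if c is None or (isinstance(c, float) and math.isnan(c)):
            c = group_carbon.get(_strip_pair_suffix(label))
        if c is None:
            missing.append(label)
            continue
        peaks.append(Peak2D(h, float(c)))
    if missing and not skip_missing_carbon:
        raise ValueError(
            "rows with neither own nor inheritable 13C shift: " + ", ".join(missing)
        )
    merged = merge_close_peaks(PeakList(peaks, label=name), merge_tol_h, merge_tol_c)
    return ReferenceCompound(name or "compound", merged, formula, mol_weight)


def merge_close_peaks(peaks: PeakList, tol_h: float, tol_c: float) -> PeakList:
    """Merge single-linkage clusters of peaks within tolerance in BOTH ppm
    dimensions to their centroid; output order is first-member order.

    Applied to a fixpoint so the operation is idempotent (a centroid that
    lands within tolerance of another cluster is merged again).
    """
    if tol_h < 0 or tol_c < 0:
        raise ValueError("merge tolerances must be >= 0")
    if tol_h == 0 and tol_c == 0:  # zero tolerance is the identity, even on
        return PeakList(list(peaks), label=peaks.label)  # duplicate coordinates
    current = list(peaks)
    while True:
        merged = _merge_once(current, tol_h, tol_c)
        if len(merged) == len(current):
            return PeakList(merged, label=peaks.label)
        current = merged


def _merge_once(peaks: list[Peak2D], tol_h: float, tol_c: float) -> list[Peak2D]:
    n = len(peaks)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    # epsilon absorbs binary-float error at decimal tolerance boundaries
    # (e.g. |0.92 - 0.89| exceeds 0.03 by ~3e-17)
    eps = 1e-9
    for i in range(n):
        for j in range(i + 1, n):
            if (
                abs(peaks[i].h_shift - peaks[j].h_shift) <= tol_h + eps
                and abs(peaks[i].c_shift - peaks[j].c_shift) <= tol_c + eps
            ):
                parent[find(j)] = find(i)

    clusters: dict[int, list[Peak2D]] = {}
    order: list[int] = []
    for i in range(n):
        r = find(i)
        if r not in clusters:
            clusters[r] = []
            order.append(r)
        clusters[r].append(peaks[i])

    out: list[Peak2D] = []
    for r in order:
        members = clusters[r]
        if len(members) == 1:
            out.append(members[0])
        else:
            h = sum(p.h_shift for p in members) / len(members)
            c = sum(p.c_shift for p in members) / len(members)
            intens = [p.intensity for p in members if p.intensity is not None]
            out.append(Peak2D(h, c, sum(intens) / len(intens) if intens else None))
    return out
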