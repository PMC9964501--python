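"""Packaged reference data: the didemnin B assignment table and a small
reference database of the compounds profiled in *Tistrella* extracts.

Didemnin B's HSQC peak list is built from its tabulated ¹H/¹³C assignments
in CD₃OD.  The other compounds' peak lists (marked ``synthetic_`` in their
filenames) are constructed stand-ins at typical chemical shifts with the
literature peak counts, shipped so the identification pipeline has a
realistic database to run against without instrument data.

Two caveats documented here rather than hidden:

* The assignment table gives no ¹³C shift for either Ist7 methylene proton
  of didemnin B, so those two correlations cannot be placed and the fixture
  peak list has 50 CH correlations at zero merge tolerance (the published
  per-compound peak count for didemnin B is 51).
* NH protons are excluded — the experiment correlates ¹H with directly
  bonded ¹³C only.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .peaks import (
    DEFAULT_MERGE_TOL_C,
    DEFAULT_MERGE_TOL_H,
    ReferenceCompound,
    ReferenceDatabase,
    build_reference_from_assignments,
    read_reference_database,
)

__all__ = [
    "didemnin_b_assignments",
    "didemnin_b_reference",
    "reference_database",
    "DIDEMNIN_B_FORMULA",
    "FIXTURE_COMPOUND_NAMES",
]

DIDEMNIN_B_FORMULA = "C57H89N7O15"

FIXTURE_COMPOUND_NAMES = (
    "methanol",
    "indole",
    "didemnin B",
    "cyclo(Pro–Tyr)",
    "Leu–Pro–Ile–Pro–Ile",
    "cyclo(Ile–Pro–Leu–Pro)",
    "n–hexane",
)


def _data_dir() -> Path:
    return Path(resources.files("atomsort") / "data")


def didemnin_b_assignments(include_nh: bool = False) -> list[dict]:
    """The packaged didemnin B assignment table as a list of row dicts
    (keys ``position``, ``h_shift``, ``c_shift``; carbon may be None)."""
    rows: list[dict] = []
    path = _data_dir() / "didemnin_b_assignments.tsv"
    with open(path, encoding="utf-8") as fh:
        header: list[str] | None = None
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                continue
            position = fields[0]
            if not include_nh and position.endswith("NH"):
                continue
            h = float(fields[1])
            c = float(fields[2]) if len(fields) > 2 and fields[2].strip() else None
            rows.append({"position": position, "h_shift": h, "c_shift": c})
    return rows


def didemnin_b_reference(
    merge_tol_h: float = DEFAULT_MERGE_TOL_H,
    merge_tol_c: float = DEFAULT_MERGE_TOL_C,
) -> ReferenceCompound:
    """Didemnin B built from the packaged assignment table.

    The Ist7a/Ist7b pair, which has no tabulated carbon, is skipped
    (see module docstring), so the zero-tolerance peak count is 50.
    """
    return build_reference_from_assignments(
        didemnin_b_assignments(),
        merge_tol_h,
        merge_tol_c,
        name="didemnin B",
        formula=DIDEMNIN_B_FORMULA,
        skip_missing_carbon=True,
    )


def reference_database() -> ReferenceDatabase:
    """The packaged seven-compound reference database."""
    return read_reference_database(_data_dir() / "reference_db")
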