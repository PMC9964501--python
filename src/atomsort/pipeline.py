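"""Identify → classify → quantify orchestration and report formats.

``run_identification`` produces the per-extract compound ranking (compound,
median d̃_AS, matched/total, label) and ``run_quantification`` turns 1D
integrals into concentration / in-tube mass / culture-titer rows for the
compounds the identification step labeled present.  Both write TSV and are
deterministic given config and inputs.  Logging goes to standard error;
report files are the only file output.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .matching import MatchConfig, rank_compounds
from .peaks import PeakList, ReferenceDatabase, read_peak_list, read_reference_database
from .quant import (
    InternalStandard,
    SampleChain,
    concentration_from_integrals,
    equivalent_volume,
    IntegralMeasurement,
    mass_in_tube,
    titer_from_tube,
)

__all__ = ["RunConfig", "run_identification", "run_quantification", "DASH"]

log = logging.getLogger("atomsort")

DASH = "–"  # placeholder for compounds that are not quantified


@dataclass(frozen=True)
class RunConfig:
    """Everything the pipeline needs beyond its input files."""

    match: MatchConfig = field(default_factory=MatchConfig)
    chain: SampleChain = field(default_factory=SampleChain)
    standard: InternalStandard = field(default_factory=lambda: InternalStandard(integral=1.0))
    report_decimals: int = 1

    def to_file(self, path) -> None:
        pairs = {
            "match_threshold": self.match.match_threshold,
            "present_threshold": self.match.present_threshold,
            "related_threshold": self.match.related_threshold,
            "range_source": self.match.range_source,
            "tube_volume": self.chain.tube_volume,
            "dissolved_volume": self.chain.dissolved_volume,
            "aliquot_fraction": self.chain.aliquot_fraction,
            "culture_volume": self.chain.culture_volume,
            "equivalent_volume_override": (
                "" if self.chain.equivalent_volume_override is None
                else self.chain.equivalent_volume_override
            ),
            "standard_integral": self.standard.integral,
            "standard_n_protons": self.standard.n_protons,
            "standard_concentration": self.standard.concentration,
            "report_decimals": self.report_decimals,
        }
        with open(path, "w", encoding="utf-8") as fh:
            for k, v in pairs.items():
                fh.write(f"{k}={v}\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        raw: dict[str, str] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}: expected key=value, got {line!r}")
                k, v = line.split("=", 1)
                raw[k.strip()] = v.strip()

        def f(key: str, default: float) -> float:
            return float(raw[key]) if key in raw and raw[key] != "" else default

        override = raw.get("equivalent_volume_override", "")
        match = MatchConfig(
            match_threshold=f("match_threshold", 0.25),
            present_threshold=f("present_threshold", 0.1),
            related_threshold=f("related_threshold", 0.2),
            range_source=raw.get("range_source", "extract"),
        )
        chain = SampleChain(
            tube_volume=f("tube_volume", 50.0),
            dissolved_volume=f("dissolved_volume", 200.0),
            aliquot_fraction=f("aliquot_fraction", 0.02),
            culture_volume=f("culture_volume", 1000.0),
            equivalent_volume_override=float(override) if override else None,
        )
        standard = InternalStandard(
            integral=f("standard_integral", 1.0),
            n_protons=int(f("standard_n_protons", 1)),
            concentration=f("standard_concentration", 150.0),
        )
        return cls(match, chain, standard, int(f("report_decimals", 1)))


def _load_extract(extract_path) -> PeakList:
    dialect = "sparky" if str(extract_path).endswith(".list") else "csv"
    return read_peak_list(extract_path, dialect=dialect)


def run_identification(
    extract_path, db_path, config: RunConfig = RunConfig(), out_path=None
) -> pd.DataFrame:
    """Rank every database compound against one extract spectrum.

    Returns (and optionally writes as TSV) a table with columns
    ``compound, median_das, matched, label`` sorted by ascending d̃_AS.
    """
    extract = _load_extract(extract_path)
    db = read_reference_database(db_path)
    log.info(
        "identification: extract %s (%d peaks) vs database %s (%d compounds); "
        "thresholds present<%.3g related<=%.3g match<=%.3g, ranges from %s",
        extract_path, len(extract), db_path, len(db),
        config.match.present_threshold, config.match.related_threshold,
        config.match.match_threshold, config.match.range_source,
    )
    matches = rank_compounds(db, extract, config.match)
    df = pd.DataFrame(
        {
            "compound": [m.compound_name for m in matches],
            "median_das": [f"{m.median_das:.3f}" for m in matches],
            "matched": [m.fraction for m in matches],
            "label": [m.label for m in matches],
        }
    )
    if out_path is not None:
        df.to_csv(out_path, sep="\t", index=False)
    return df


def _read_integrals(integrals_path) -> dict[str, IntegralMeasurement]:
    table = pd.read_csv(integrals_path, sep="\t", comment="#")
    required = {"compound", "integral", "n_protons"}
    if not required.issubset(table.columns):
        raise ValueError(
            f"{integrals_path}: integral table needs columns {sorted(required)}"
        )
    out = {}
    for row in table.itertuples(index=False):
        out[str(row.compound)] = IntegralMeasurement(
            str(row.compound), float(row.integral), int(row.n_protons)
        )
    return out


def run_quantification(
    identification,
    integrals_path,
    db_path,
    config: RunConfig = RunConfig(),
    out_path=None,
) -> pd.DataFrame:
    """Quantify the compounds labeled ``present`` in an identification report.

    ``identification`` is the DataFrame from :func:`run_identification` or a
    path to its TSV.  Compounds not labeled present (or lacking an integral
    row) get dash rows.  A present compound with an integral but neither a
    molecular weight nor a formula in the database is an error.
    """
    if not isinstance(identification, pd.DataFrame):
        identification = pd.read_csv(identification, sep="\t")
    db = read_reference_database(db_path)
    integrals = _read_integrals(integrals_path)
    eq_vol = equivalent_volume(config.chain)
    dec = config.report_decimals
    log.info(
        "quantification: %d identified compounds, %d integrals, tube %.3g uL, "
        "equivalent culture volume %.4g mL",
        len(identification), len(integrals), config.chain.tube_volume, eq_vol,
    )

    rows = []
    for rec in identification.itertuples(index=False):
        name, label = str(rec.compound), str(rec.label)
        if label != "present" or name not in integrals:
            rows.append(
                {"compound": name, "label": label,
                 "concentration_mM": DASH, "mass_ug": DASH, "titer_mg_per_L": DASH}
            )
            continue
        comp = db[name]
        mw = comp.resolve_mol_weight()  # raises if neither MW nor formula
        conc = concentration_from_integrals(integrals[name], config.standard)
        mass = mass_in_tube(conc, config.chain.tube_volume, mw)
        titer = titer_from_tube(mass, eq_vol)
        rows.append(
            {
                "compound": name,
                "label": label,
                "concentration_mM": f"{conc:.{dec}f}",
                "mass_ug": f"{mass:.{dec}f}",
                "titer_mg_per_L": f"{titer:.{dec}f}",
            }
        )
    df = pd.DataFrame(
        rows, columns=["compound", "label", "concentration_mM", "mass_ug", "titer_mg_per_L"]
    )
    if out_path is not None:
        df.to_csv(out_path, sep="\t", index=False)
    return df
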