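"""Synthetic HSQC extracts with known ground truth.

The generator emulates what matters for testing identification and
quantification end-to-end: a reference database of compounds with peak lists
in realistic spectral windows, crude-extract spectra built as jittered,
dropout-thinned unions of the present compounds' peaks plus uniform decoy
peaks (standing in for the ~50% of extract peaks that remain unassigned),
and 1D integral tables consistent with assigned concentrations.  Everything
is deterministic given the seed.

Default conditions mirror the observed extract scale: a few present
compounds of 5–55 peaks each plus 125 decoys gives 200–250 peaks per
extract.  Jitter defaults (0.01 ppm ¹H, 0.1 ppm ¹³C) are typical
referencing/temperature scatter between runs; dropout (5%) models weak or
overlapped peaks that the peak picker misses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .masses import average_mass, format_formula, parse_formula, Formula
from .peaks import Peak2D, PeakList, ReferenceCompound, ReferenceDatabase
from .quant import InternalStandard

__all__ = [
    "SimParams",
    "SimTruth",
    "simulate_reference_db",
    "simulate_extract",
    "simulate_integrals",
]


@dataclass(frozen=True)
class SimParams:
    """Generator settings; ``seed`` fully determines all outputs."""

    n_compounds: int = 8
    peaks_per_compound: tuple[int, int] = (5, 55)
    h_window: tuple[float, float] = (0.0, 10.0)
    c_window: tuple[float, float] = (0.0, 160.0)
    jitter_h: float = 0.01  # ppm sd
    jitter_c: float = 0.1  # ppm sd
    dropout_prob: float = 0.05
    n_decoys: int = 125
    integral_noise_cv: float = 0.0
    concentration_range: tuple[float, float] = (2.0, 30.0)  # mM, Table-4 scale
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds < 1:
            raise ValueError("n_compounds must be >= 1 (database must be nonempty)")
        lo, hi = self.peaks_per_compound
        if not (1 <= lo <= hi):
            raise ValueError("invalid peaks_per_compound range")
        if self.h_window[0] >= self.h_window[1] or self.c_window[0] >= self.c_window[1]:
            raise ValueError("spectral windows must be nonempty")
        if not (0 <= self.dropout_prob < 1):
            raise ValueError("dropout_prob must be in [0, 1)")
        if self.n_decoys < 0 or self.integral_noise_cv < 0:
            raise ValueError("n_decoys and integral_noise_cv must be >= 0")


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated extract."""

    present_names: list[str]
    true_concentrations: dict[str, float]  # mM
    decoy_indices: list[int]  # indices into the shuffled extract list
    params: SimParams

    def to_json(self) -> str:
        d = {
            "present_names": self.present_names,
            "true_concentrations": self.true_concentrations,
            "decoy_indices": self.decoy_indices,
            "params": asdict(self.params),
        }
        return json.dumps(d, indent=2)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stream]))


def _synthetic_formula(rng: np.random.Generator) -> str:
    # peptide-like CHNO composition; mol_weight is computed from it so the
    # (formula, mol_weight) pair is consistent by construction
    c = int(rng.integers(5, 60))
    h = int(rng.integers(c, 2 * c + 2))
    n = int(rng.integers(0, 8))
    o = int(rng.integers(1, 16))
    parts = [f"C{c}", f"H{h}"]
    if n:
        parts.append(f"N{n}")
    parts.append(f"O{o}")
    return "".join(parts)


def simulate_reference_db(params: SimParams) -> ReferenceDatabase:
    """Database of ``n_compounds`` compounds with uniform peaks in the
    spectral windows and consistent synthetic formula/MW metadata."""
    rng = _rng(params.seed, 1)
    compounds = []
    lo, hi = params.peaks_per_compound
    for i in range(params.n_compounds):
        n_peaks = int(rng.integers(lo, hi + 1))
        h = rng.uniform(*params.h_window, n_peaks)
        c = rng.uniform(*params.c_window, n_peaks)
        formula = _synthetic_formula(rng)
        mw = average_mass(parse_formula(formula))
        peaks = PeakList(
            [Peak2D(float(a), float(b)) for a, b in zip(h, c)], label=f"SIM-{i:03d}"
        )
        compounds.append(
            ReferenceCompound(f"SIM-{i:03d}", peaks, formula, round(mw, 2))
        )
    return ReferenceDatabase(compounds)


def simulate_extract(
    db: ReferenceDatabase, present: Iterable[str], params: SimParams
) -> tuple[PeakList, SimTruth]:
    """Extract spectrum = jittered, dropout-thinned peaks of the present
    compounds plus ``n_decoys`` uniform decoys, deterministically shuffled."""
    present = list(present)
    unknown = [n for n in present if n not in db]
    if unknown:
        raise ValueError(f"present compounds not in database: {unknown}")
    rng = _rng(params.seed, 2)

    peaks: list[Peak2D] = []
    is_decoy: list[bool] = []
    for name in present:
        for p in db[name].peaks:
            if rng.random() < params.dropout_prob:
                continue
            h = p.h_shift + rng.normal(0.0, params.jitter_h) if params.jitter_h else p.h_shift
            c = p.c_shift + rng.normal(0.0, params.jitter_c) if params.jitter_c else p.c_shift
            peaks.append(Peak2D(float(h), float(c)))
            is_decoy.append(False)
    for _ in range(params.n_decoys):
        peaks.append(
            Peak2D(float(rng.uniform(*params.h_window)), float(rng.uniform(*params.c_window)))
        )
        is_decoy.append(True)

    order = rng.permutation(len(peaks))
    shuffled = [peaks[i] for i in order]
    decoy_indices = sorted(int(j) for j, i in enumerate(order) if is_decoy[i])

    concs = {
        name: float(np.round(rng.uniform(*params.concentration_range), 3))
        for name in present
    }
    truth = SimTruth(
        present_names=present,
        true_concentrations=concs,
        decoy_indices=decoy_indices,
        params=params,
    )
    return PeakList(shuffled, label=f"sim-extract-{params.seed}"), truth


def simulate_integrals(
    truth: SimTruth,
    standard: InternalStandard,
    params: SimParams | None = None,
    n_protons: int = 3,
) -> pd.DataFrame:
    """Integral table (compound, integral, n_protons) consistent with the
    assigned concentrations; absent compounds get no rows.

    integral = c_true/c_std · I_std · n_protons · (1 + ε),
    ε ~ Normal(0, integral_noise_cv).
    """
    params = params or truth.params
    rng = _rng(params.seed, 3)
    rows = []
    for name in truth.present_names:
        conc = truth.true_concentrations[name]
        integral = conc / standard.concentration * standard.integral * n_protons
        if params.integral_noise_cv > 0:
            integral *= 1.0 + rng.normal(0.0, params.integral_noise_cv)
        rows.append({"compound": name, "integral": integral, "n_protons": n_protons})
    return pd.DataFrame(rows, columns=["compound", "integral", "n_protons"])
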