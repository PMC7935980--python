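"""Counting statistics for magnetic-bead-assembly (MBA) assays.

In an MBA assay the analyte links functionalized beads into aggregates;
after on-chip separation the fraction of aggregates among ~100 counted
beads reports the analyte concentration.  This module provides binomial
aggregate-fraction estimates with Wilson 95% intervals, separation
efficiency summaries, dose–response tables (no monotonicity is imposed:
excess analyte saturates binding sites and the response hooks downward),
NLM-versus-flow-cytometry comparison, and a seeded synthetic population
generator for end-to-end protocol tests.

The reference dose–response table shipped with the package stores
published point estimates with their printed ± values kept verbatim as
metadata (their type — SD, SEM or range — is not reinterpreted).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import (
    confint_proportions_2indep,
    proportion_confint,
    test_proportions_2indep,
)

from .geometry import ArraySpec
from .particles import BeadSpec, DimerSpec, Population

__all__ = [
    "AssayCounts",
    "DoseResponse",
    "aggregate_fraction",
    "efficiency_summary",
    "synth_population",
    "method_comparison",
    "load_reference_counts",
]


@dataclass(frozen=True)
class AssayCounts:
    """Bead counts for one assay condition (default 100 beads counted)."""

    label: str
    concentration_mol_dm3: float
    n_total: int
    n_aggregate: int
    method: str = "nlm"

    def __post_init__(self):
        if self.method not in ("nlm", "cytometry"):
            raise ValueError("method must be 'nlm' or 'cytometry'")
        if self.n_total <= 0:
            raise ValueError("n_total must be positive")
        if not 0 <= self.n_aggregate <= self.n_total:
            raise ValueError("need 0 <= n_aggregate <= n_total")


def aggregate_fraction(counts: AssayCounts) -> tuple[float, tuple[float, float]]:
    """Aggregate percentage with a Wilson 95% interval.

    Returns ``(point_pct, (lo_pct, hi_pct))``.
    """
    lo, hi = proportion_confint(
        counts.n_aggregate, counts.n_total, alpha=0.05, method="wilson"
    )
    pct = 100.0 * counts.n_aggregate / counts.n_total
    return pct, (100.0 * float(lo), 100.0 * float(hi))


def efficiency_summary(epsilons: list[float]) -> tuple[float, float]:
    """Mean and sample standard deviation of separation efficiencies.

    Accepts plain ε values or objects exposing ``.epsilon``.  A single
    result yields an undefined (NaN) standard deviation.
    """
    if len(epsilons) == 0:
        raise ValueError("need at least one separation result")
    vals = np.array(
        [e.epsilon if hasattr(e, "epsilon") else float(e) for e in epsilons]
    )
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else float("nan")
    return mean, sd


def synth_population(
    n: int,
    dimer_fraction: float,
    stick_prob: float = 0.0,
    seed: int | None = None,
    array: ArraySpec | None = None,
    monomer: BeadSpec | None = None,
    dimer: DimerSpec | None = None,
    n_start_columns: int = 2,
) -> Population:
    """Seeded synthetic monomer/dimer population on an array's start rows.

    Species labels are i.i.d. Bernoulli(``dimer_fraction``); monomers are
    additionally flagged stuck with probability ``stick_prob`` (nonspecific
    surface adhesion).  Particles are placed on magnet centres of the first
    ``n_start_columns`` lattice columns.  Identical seeds give identical
    populations.
    """
    if n <= 0:
        raise ValueError("population size must be positive")
    if not 0.0 <= dimer_fraction <= 1.0 or not 0.0 <= stick_prob <= 1.0:
        raise ValueError("fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    is_dimer = rng.random(n) < dimer_fraction
    species = ["dimer" if d else "monomer" for d in is_dimer]
    if array is None:
        from .geometry import standard_array

        array = standard_array("S", n_x=40, n_y=10)
    cols = rng.integers(0, min(n_start_columns, array.n_x), n)
    rows = rng.integers(0, array.n_y, n)
    positions = np.column_stack(
        [
            array.origin_um[0] + cols * array.pitch_x_um,
            array.origin_um[1] + rows * array.pitch_y_um,
        ]
    ).astype(float)
    stuck = (rng.random(n) < stick_prob) & ~is_dimer
    return Population(
        species=species,
        positions_um=positions,
        monomer=monomer or BeadSpec(),
        dimer=dimer or DimerSpec(),
        stuck=stuck,
    )


@dataclass
class DoseResponse:
    """Aggregate percentages across analyte concentrations for one method.

    Conditions are sorted by concentration.  No monotonicity is imposed —
    hook-effect (non-monotone) responses are first-class.
    """

    analyte: str
    method: str
    concentrations_mol_dm3: np.ndarray
    aggregate_pct: np.ndarray
    interval_lo_pct: np.ndarray
    interval_hi_pct: np.ndarray
    counts: list[AssayCounts] | None = None

    def __post_init__(self):
        order = np.argsort(self.concentrations_mol_dm3)
        self.concentrations_mol_dm3 = np.asarray(self.concentrations_mol_dm3, float)[order]
        self.aggregate_pct = np.asarray(self.aggregate_pct, float)[order]
        self.interval_lo_pct = np.asarray(self.interval_lo_pct, float)[order]
        self.interval_hi_pct = np.asarray(self.interval_hi_pct, float)[order]
        if self.counts is not None:
            self.counts = [self.counts[i] for i in order]
        if np.any(self.aggregate_pct < 0) or np.any(self.aggregate_pct > 100):
            raise ValueError("percentages must lie in [0, 100]")

    @classmethod
    def from_counts(cls, analyte: str, counts: list[AssayCounts]) -> "DoseResponse":
        pct, lo, hi = [], [], []
        for c in counts:
            p, (l, h) = aggregate_fraction(c)
            pct.append(p)
            lo.append(l)
            hi.append(h)
        return cls(
            analyte=analyte,
            method=counts[0].method,
            concentrations_mol_dm3=np.array([c.concentration_mol_dm3 for c in counts]),
            aggregate_pct=np.array(pct),
            interval_lo_pct=np.array(lo),
            interval_hi_pct=np.array(hi),
            counts=list(counts),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "concentration_mol_dm3": self.concentrations_mol_dm3,
                "aggregate_pct": self.aggregate_pct,
                "interval_lo_pct": self.interval_lo_pct,
                "interval_hi_pct": self.interval_hi_pct,
                "method": self.method,
            }
        )


def method_comparison(nlm: DoseResponse, cytometry: DoseResponse) -> pd.DataFrame:
    """Per-condition difference between two dose–response tables.

    Differences are ``nlm − cytometry`` in percentage points.  When both
    tables carry raw counts a two-proportion score test and a Newcombe
    interval for the difference are included; otherwise those columns are
    NaN.  Condition sets must match exactly.
    """
    a = set(np.round(np.log10(nlm.concentrations_mol_dm3), 6))
    b = set(np.round(np.log10(cytometry.concentrations_mol_dm3), 6))
    if a != b:
        raise ValueError(
            f"condition mismatch: only in first {sorted(a - b)}, "
            f"only in second {sorted(b - a)}"
        )
    rows = []
    for i, conc in enumerate(nlm.concentrations_mol_dm3):
        j = int(np.argmin(np.abs(cytometry.concentrations_mol_dm3 - conc)))
        diff = nlm.aggregate_pct[i] - cytometry.aggregate_pct[j]
        lo = hi = pval = float("nan")
        if nlm.counts is not None and cytometry.counts is not None:
            c1, c2 = nlm.counts[i], cytometry.counts[j]
            l, h = confint_proportions_2indep(
                c1.n_aggregate, c1.n_total, c2.n_aggregate, c2.n_total,
                method="newcomb", compare="diff",
            )
            lo, hi = 100.0 * float(l), 100.0 * float(h)
            res = test_proportions_2indep(
                c1.n_aggregate, c1.n_total, c2.n_aggregate, c2.n_total,
                method="score", compare="diff",
            )
            pval = float(res.pvalue)
        rows.append(
            {
                "concentration_mol_dm3": conc,
                "nlm_pct": nlm.aggregate_pct[i],
                "cytometry_pct": cytometry.aggregate_pct[j],
                "difference_pct_points": diff,
                "diff_ci_lo_pct": lo,
                "diff_ci_hi_pct": hi,
                "p_value": pval,
            }
        )
    return pd.DataFrame(rows)


def load_reference_counts(analyte: str = "BBSA", method: str = "nlm") -> DoseResponse:
    """Published on-chip dose–response tables bundled with the package.

    Available analytes: ``BBSA`` (model protein; hook-effect response
    peaking at 1e-9 mol/dm³) and ``dsDNA`` (viral gene fragment).  The
    ``reported_pm_pct`` column of the underlying CSV preserves the printed
    ± values as-is; the intervals carried by the returned table are those
    values around the point estimates, not recomputed Wilson intervals.
    """
    ref = importlib.resources.files("nlmsim.data") / "reference_dose_response.csv"
    df = pd.read_csv(str(ref))
    sel = df[(df["analyte"] == analyte) & (df["method"] == method)]
    if sel.empty:
        known = sorted(df["analyte"].unique())
        raise ValueError(f"no reference table for {analyte!r}/{method!r}; analytes: {known}")
    return DoseResponse(
        analyte=analyte,
        method=method,
        concentrations_mol_dm3=sel["concentration_mol_dm3"].to_numpy(),
        aggregate_pct=sel["aggregate_pct"].to_numpy(),
        interval_lo_pct=(sel["aggregate_pct"] - sel["reported_pm_pct"]).clip(0).to_numpy(),
        interval_hi_pct=(sel["aggregate_pct"] + sel["reported_pm_pct"]).clip(upper=100).to_numpy(),
    )
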