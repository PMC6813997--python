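"""Ecological correlates of convergent regimes: chi-square tests and ANOVA.

Regime membership (one regime at a time, in-regime vs all other species) is
cross-tabulated against categorical ecological factors — habitat, diet,
feeding behaviour, dive type — with Pearson chi-square tests.  Species that
belong to several categories of a factor (e.g. both nearshore and oceanic)
are handled by *assignment variants*: the analysis is repeated with every
ambiguous species fixed to its first listed category, then its second, and
so on, one factor at a time.  All tests run for a regime are Bonferroni
corrected by the realised test count.  Body sizes are compared across
groups by one-way ANOVA of natural-log-transformed masses.
"""
from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EcologyTable",
    "AssociationResult",
    "chi_square_tests",
    "body_size_anova",
    "FACTORS",
]

FACTORS = ("habitat", "diet", "feeding", "dive")

HABITATS = ("riverine", "nearshore", "oceanic")
DIETS = ("generalist", "fish", "cephalopods")
FEEDING = ("raptorial", "suction")
DIVES = ("shallow", "mid", "deep", "very deep")  # ordered by max dive depth

_ALLOWED = {
    "habitat": set(HABITATS),
    "diet": set(DIETS),
    "feeding": set(FEEDING),
    "dive": set(DIVES),
}


@dataclasses.dataclass
class EcologyTable:
    """Species ecology: multi-valued categorical factors plus body mass (kg).

    ``data`` is a DataFrame indexed by species with columns habitat, diet,
    feeding, dive (each a string, multiple values separated by ``|``) and
    mass_kg (> 0).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        needed = set(FACTORS) | {"mass_kg"}
        missing = needed - set(self.data.columns)
        if missing:
            raise ValueError(f"ecology table missing columns: {sorted(missing)}")
        if (self.data["mass_kg"] <= 0).any():
            bad = self.data.index[self.data["mass_kg"] <= 0].tolist()
            raise ValueError(f"non-positive body mass for: {bad}")
        for f in FACTORS:
            for sp, cell in self.data[f].items():
                cats = parse_cell(cell)
                if not cats:
                    raise ValueError(f"species {sp!r} has no {f} category")
                unknown = [c for c in cats if c not in _ALLOWED[f]]
                if unknown:
                    raise ValueError(f"unknown {f} categor(ies) {unknown} for {sp!r}")

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    def categories(self, species: str, factor: str) -> list[str]:
        return parse_cell(self.data.loc[species, factor])

    @staticmethod
    def read_csv(path) -> "EcologyTable":
        return EcologyTable(pd.read_csv(path, index_col=0))

    def to_csv(self, path) -> None:
        self.data.to_csv(path)


def parse_cell(cell: str) -> list[str]:
    """Split a possibly multi-valued cell ('nearshore|oceanic') into categories."""
    return [c.strip() for c in str(cell).split("|") if c.strip()]


@dataclasses.dataclass(frozen=True)
class AssociationResult:
    """One chi-square test of regime membership against one factor variant."""

    regime: str
    factor: str
    variant: int
    chi2: float | None
    df: int | None
    p_raw: float | None
    p_bonferroni: float | None
    n_tests: int
    skipped: bool = False
    note: str = ""

    def to_row(self) -> dict:
        return dataclasses.asdict(self)


def _variant_assignment(
    ecology: EcologyTable, factor: str, variant: int
) -> dict[str, str]:
    """Fix every species to one category: its ``variant``-th listed one
    (clamped to its own list length)."""
    out = {}
    for sp in ecology.species:
        cats = ecology.categories(sp, factor)
        out[sp] = cats[min(variant, len(cats) - 1)]
    return out


def chi_square_tests(
    membership: Mapping[str, str],
    ecology: EcologyTable,
    regime: str,
) -> list[AssociationResult]:
    """Pearson chi-square tests of membership in ``regime`` vs each factor.

    Membership maps species to a regime label (non-convergent species may
    carry any other label).  For each factor, one test per assignment
    variant is run; categories with an empty margin are dropped (recorded
    in the result note) and a test with fewer than two remaining categories
    is skipped.  Bonferroni correction multiplies each raw p by the total
    number of tests actually run for this regime.
    """
    sp_order = ecology.species
    missing = [s for s in sp_order if s not in membership]
    if missing:
        raise ValueError(f"membership missing for species: {missing[:5]}")
    in_regime = np.array([membership[s] == regime for s in sp_order])
    if in_regime.sum() == 0:
        raise ValueError(f"no species belong to regime {regime!r}")

    prelim: list[AssociationResult] = []
    for factor in FACTORS:
        n_variants = max(len(ecology.categories(s, factor)) for s in sp_order)
        for variant in range(n_variants):
            assign = _variant_assignment(ecology, factor, variant)
            cats = sorted({assign[s] for s in sp_order})
            table = np.zeros((2, len(cats)), dtype=float)
            for i, s in enumerate(sp_order):
                table[0 if in_regime[i] else 1, cats.index(assign[s])] += 1
            col_ok = table.sum(axis=0) > 0
            note = ""
            if not col_ok.all():
                dropped = [c for c, ok in zip(cats, col_ok) if not ok]
                note = f"dropped empty categories: {dropped}"
                table = table[:, col_ok]
            if table.shape[1] < 2 or (table.sum(axis=1) == 0).any():
                prelim.append(
                    AssociationResult(
                        regime=regime, factor=factor, variant=variant,
                        chi2=None, df=None, p_raw=None, p_bonferroni=None,
                        n_tests=0, skipped=True,
                        note=note or "fewer than 2 informative categories",
                    )
                )
                continue
            res = stats.chi2_contingency(table, correction=False)
            prelim.append(
                AssociationResult(
                    regime=regime, factor=factor, variant=variant,
                    chi2=float(res.statistic), df=int(res.dof),
                    p_raw=float(res.pvalue), p_bonferroni=None,
                    n_tests=0, note=note,
                )
            )
    n_tests = sum(1 for r in prelim if not r.skipped)
    out = []
    for r in prelim:
        if r.skipped:
            out.append(dataclasses.replace(r, n_tests=n_tests))
        else:
            out.append(
                dataclasses.replace(
                    r,
                    n_tests=n_tests,
                    p_bonferroni=min(1.0, r.p_raw * n_tests),
                )
            )
    return out


def association_table(results: Sequence[AssociationResult]) -> pd.DataFrame:
    """Tidy results table (one row per test)."""
    return pd.DataFrame([r.to_row() for r in results])


def body_size_anova(
    masses: Mapping[str, float],
    groups: Mapping[str, str],
) -> tuple[float, int, int, float]:
    """One-way ANOVA of natural-log body masses across groups.

    Returns ``(F, df1, df2, p)``.  Computed from explicit between/within
    sums of squares (so SST = SSB + SSW holds by construction).
    """
    species = sorted(masses)
    missing = [s for s in species if s not in groups]
    if missing:
        raise ValueError(f"group missing for species: {missing[:5]}")
    vals = np.array([masses[s] for s in species], dtype=float)
    if (vals <= 0).any():
        raise ValueError("masses must be positive for log transform")
    y = np.log(vals)
    labels = np.array([groups[s] for s in species])
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    grand = y.mean()
    ssb = ssw = 0.0
    for g in uniq:
        yg = y[labels == g]
        ssb += yg.size * (yg.mean() - grand) ** 2
        ssw += float(((yg - yg.mean()) ** 2).sum())
    df1 = len(uniq) - 1
    df2 = y.size - len(uniq)
    if df2 <= 0:
        raise ValueError("no within-group degrees of freedom")
    if ssw == 0.0:
        raise ValueError("zero within-group variance in all groups; F undefined")
    F = (ssb / df1) / (ssw / df2)
    p = float(stats.f.sf(F, df1, df2))
    return float(F), df1, df2, p
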