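"""Region-wise concordance statistics between simulated and clinically
mapped driver-harboring regions.

Each of the 7 atrial regions of each patient falls into one of four
mutually exclusive categories: ``both`` (drivers seen by simulation and by
clinical mapping), ``sim_only`` (a latent driver site: the substrate
sustains a rotor in simulation but none was mapped clinically),
``firm_only`` (mapped clinically but not reproduced in simulation), or
``neither``.  On top of that table the module provides the cohort summary
conventions (median [IQR] under selectable quantile definitions), agreement
kappas on the pooled 2×2 table, and exact nonparametric tests (Wilcoxon
signed-rank for paired counts, Mann–Whitney for outcome-group comparisons)
implemented by full enumeration with the usual tie handling.

An 11-patient reference cohort with ablation outcomes ships with the
package (``load_cohort_fixture``).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES",
    "RegionClassTable",
    "CohortFixture",
    "classify_regions",
    "load_cohort_fixture",
    "summarize_cohort",
    "quantiles",
    "median_iqr",
    "kappa",
    "wilcoxon_signed_rank",
    "mann_whitney",
    "group_comparison",
]

CATEGORIES = ("both", "sim_only", "firm_only", "neither")
N_REGIONS = 7


class UndefinedTestError(ValueError):
    """The requested statistic is undefined for this input."""


@dataclass
class RegionClassTable:
    """Long-format (patient, region, category) table with count helpers."""

    rows: pd.DataFrame     # columns: patient, region, category

    def __post_init__(self):
        need = {"patient", "region", "category"}
        if not need <= set(self.rows.columns):
            raise ValueError(f"rows must have columns {sorted(need)}")
        bad = set(self.rows["category"]) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown categories: {sorted(bad)}")

    @property
    def patients(self) -> list:
        return list(dict.fromkeys(self.rows["patient"]))

    def counts(self) -> pd.DataFrame:
        """Per-patient counts of each category plus derived columns."""
        c = (self.rows.pivot_table(index="patient", columns="category",
                                   aggfunc="size", fill_value=0)
             .reindex(columns=CATEGORIES, fill_value=0))
        c = c.loc[self.patients]
        c["sim"] = c["both"] + c["sim_only"]
        c["firm"] = c["both"] + c["firm_only"]
        c["agreed"] = c["both"] + c["neither"]
        c["differed"] = c["sim_only"] + c["firm_only"]
        return c

    def pooled_2x2(self) -> tuple[int, int, int, int]:
        """(both, sim_only, firm_only, neither) pooled over patients."""
        c = self.counts()
        return (int(c["both"].sum()), int(c["sim_only"].sum()),
                int(c["firm_only"].sum()), int(c["neither"].sum()))

    @classmethod
    def from_counts(cls, counts: pd.DataFrame) -> "RegionClassTable":
        """Reconstruct a long table from per-patient category counts
        (regions are assigned ids 1..7 in category order)."""
        rows = []
        for patient, row in counts.iterrows():
            region = 1
            for cat in CATEGORIES:
                for _ in range(int(row[cat])):
                    rows.append((patient, region, cat))
                    region += 1
        return cls(pd.DataFrame(rows, columns=["patient", "region",
                                               "category"]))


@dataclass
class CohortFixture:
    """A region-classification table plus per-patient ablation outcome."""

    table: RegionClassTable
    outcome: dict            # patient -> "success" | "failure"


def classify_regions(sim_regions: dict, firm_regions: dict,
                     all_regions: set[int]) -> RegionClassTable:
    """Four-category classification by set membership.

    ``sim_regions`` and ``firm_regions`` map patient → set of region ids in
    which each modality observed drivers.
    """
    rows = []
    for patient in sim_regions:
        s = set(sim_regions[patient])
        f = set(firm_regions.get(patient, set()))
        for bad in (s | f) - all_regions:
            raise ValueError(f"unknown region id {bad!r} for patient {patient!r}")
        for r in sorted(all_regions):
            if r in s and r in f:
                cat = "both"
            elif r in s:
                cat = "sim_only"
            elif r in f:
                cat = "firm_only"
            else:
                cat = "neither"
            rows.append((patient, r, cat))
    return RegionClassTable(pd.DataFrame(rows, columns=["patient", "region",
                                                        "category"]))


def load_cohort_fixture() -> CohortFixture:
    """The bundled 11-patient reference cohort."""
    with resources.files("rotorsim.data").joinpath("cohort_fixture.csv").open() as fh:
        df = pd.read_csv(fh, comment="#")
    counts = df.set_index("patient")[["both", "neither", "sim_only",
                                      "firm_only"]]
    table = RegionClassTable.from_counts(counts)
    outcome = dict(zip(df["patient"], df["outcome"]))
    return CohortFixture(table=table, outcome=outcome)


# ---------------------------------------------------------------------------
# quantile conventions
# ---------------------------------------------------------------------------

def quantiles(values, p: float, method: str = "type6") -> float:
    """Quantile under a named convention.

    ``type6``: rank h = (n+1)p with linear interpolation (the convention of
    common clinical statistics packages); ``type7``: h = (n−1)p + 1;
    ``tukey_hinges``: fold-median hinges (exact quarters only).
    """
    x = np.sort(np.asarray(values, dtype=float))
    if x.size == 0:
        raise ValueError("values must be non-empty")
    if method == "type6":
        return float(np.quantile(x, p, method="weibull"))
    if method == "type7":
        return float(np.quantile(x, p, method="linear"))
    if method == "tukey_hinges":
        if p == 0.5:
            return float(np.median(x))
        n = x.size
        half = (n + 1) // 2
        lower, upper = x[:half], x[n - half:]
        if p == 0.25:
            return float(np.median(lower))
        if p == 0.75:
            return float(np.median(upper))
        raise ValueError("tukey_hinges defines p in {0.25, 0.5, 0.75} only")
    raise ValueError(f"unknown quantile method {method!r}")


def median_iqr(values, method: str = "type6") -> tuple[float, float, float]:
    """(median, q1, q3) under the given convention."""
    return (quantiles(values, 0.5, method), quantiles(values, 0.25, method),
            quantiles(values, 0.75, method))


# ---------------------------------------------------------------------------
# agreement
# ---------------------------------------------------------------------------

def kappa(table: RegionClassTable, method: str = "cohen") -> float:
    """Agreement between the two modalities on the pooled 2×2 region table.

    ``cohen``: chance-corrected with product marginals; ``pabak``:
    prevalence-and-bias-adjusted (2·p₀ − 1); ``prevalence_bias_adjusted`` is
    an alias for ``pabak``.
    """
    a, b, c, d = table.pooled_2x2()      # both, sim_only, firm_only, neither
    n = a + b + c + d
    if n == 0:
        raise UndefinedTestError("empty table")
    p0 = (a + d) / n
    if method in ("pabak", "prevalence_bias_adjusted"):
        return 2.0 * p0 - 1.0
    if method == "cohen":
        sim_yes, firm_yes = a + b, a + c
        pe = (sim_yes * firm_yes + (n - sim_yes) * (n - firm_yes)) / n ** 2
        if pe >= 1.0:
            raise UndefinedTestError("degenerate marginals: kappa undefined")
        return (p0 - pe) / (1.0 - pe)
    raise ValueError(f"unknown kappa method {method!r}")


# ---------------------------------------------------------------------------
# exact nonparametric tests
# ---------------------------------------------------------------------------

def _signed_rank_stat(diffs: np.ndarray) -> tuple[float, np.ndarray]:
    """W+ with zero differences dropped and mid-ranked ties."""
    nz = diffs[diffs != 0]
    if nz.size == 0:
        raise UndefinedTestError("all paired differences are zero")
    ranks = pd.Series(np.abs(nz)).rank(method="average").to_numpy()
    w_plus = float(ranks[nz > 0].sum())
    return w_plus, ranks


def wilcoxon_signed_rank(paired_a, paired_b,
                         mode: str = "exact") -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test; returns (W+, p).

    ``exact`` enumerates all 2^m sign assignments of the nonzero
    differences (m ≤ 20); ``approx`` uses the tie-corrected normal
    approximation.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    diffs = a - b
    w_plus, ranks = _signed_rank_stat(diffs)
    m = ranks.size
    total = float(ranks.sum())
    mu = total / 2.0
    if mode == "exact":
        if m < 5:
            raise UndefinedTestError("exact mode requires >= 5 nonzero pairs")
        if m > 20:
            raise ValueError("exact enumeration limited to m <= 20")
        dev = abs(w_plus - mu)
        count = 0
        for signs in itertools.product((0.0, 1.0), repeat=m):
            w = float(np.dot(signs, ranks))
            if abs(w - mu) >= dev - 1e-12:
                count += 1
        return w_plus, count / 2.0 ** m
    if mode == "approx":
        # tie-corrected variance of W+
        _, tie_counts = np.unique(np.abs(diffs[diffs != 0]),
                                  return_counts=True)
        var = (m * (m + 1) * (2 * m + 1)
               - 0.5 * np.sum(tie_counts ** 3 - tie_counts)) / 24.0
        from scipy.stats import norm
        z = (w_plus - mu) / np.sqrt(var)
        return w_plus, float(2.0 * norm.sf(abs(z)))
    raise ValueError(f"unknown mode {mode!r}")


def _u_stat(x: np.ndarray, y: np.ndarray) -> float:
    """Mann–Whitney U for x over y with half credit for ties."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def mann_whitney(group_a, group_b,
                 mode: str = "exact_permutation") -> tuple[float, float]:
    """Two-sided Mann–Whitney test; returns (U for group_a, p).

    ``exact_permutation`` enumerates all C(n, n_a) group assignments;
    ``tie_corrected_normal`` applies the tie-corrected normal approximation
    without continuity correction.
    """
    x = np.asarray(group_a, dtype=float)
    y = np.asarray(group_b, dtype=float)
    if x.size == 0 or y.size == 0:
        raise UndefinedTestError("both groups must be non-empty")
    u_obs = _u_stat(x, y)
    n1, n2 = x.size, y.size
    mu = n1 * n2 / 2.0
    if mode == "exact_permutation":
        pooled = np.concatenate([x, y])
        n = pooled.size
        dev = abs(u_obs - mu)
        count = 0
        total = 0
        idx = np.arange(n)
        for comb in itertools.combinations(idx, n1):
            sel = np.zeros(n, dtype=bool)
            sel[list(comb)] = True
            u = _u_stat(pooled[sel], pooled[~sel])
            total += 1
            if abs(u - mu) >= dev - 1e-12:
                count += 1
        return u_obs, count / total
    if mode == "tie_corrected_normal":
        pooled = np.concatenate([x, y])
        n = pooled.size
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = np.sum(tie_counts ** 3 - tie_counts) / (n * (n - 1))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            raise UndefinedTestError("zero variance: all values tied")
        from scipy.stats import norm
        z = (u_obs - mu) / np.sqrt(var)
        return u_obs, float(2.0 * norm.sf(abs(z)))
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# cohort summaries
# ---------------------------------------------------------------------------

def summarize_cohort(table: RegionClassTable,
                     method: str = "type6") -> dict:
    """Cohort totals and per-patient median [IQR] summaries."""
    c = table.counts()
    out = {
        "totals": {
            "sim": int(c["sim"].sum()),
            "firm": int(c["firm"].sum()),
            "both": int(c["both"].sum()),
            "neither": int(c["neither"].sum()),
            "agreed": int(c["agreed"].sum()),
            "differed": int(c["differed"].sum()),
            "latent": int(c["sim_only"].sum()),
            "firm_only": int(c["firm_only"].sum()),
        },
        "per_patient": {},
    }
    for col in ("sim", "firm", "agreed", "differed", "sim_only",
                "firm_only", "both", "neither"):
        med, q1, q3 = median_iqr(c[col].to_numpy(), method)
        out["per_patient"][col] = {"median": med, "iqr": [q1, q3]}
    return out


def group_comparison(fixture: CohortFixture, method: str = "type6",
                     mw_mode: str = "tie_corrected_normal") -> dict:
    """Per-outcome medians/IQRs with Mann–Whitney p-values.

    Compares per-patient counts of simulated-driver regions, clinically
    mapped driver regions, and latent (sim-only) regions between outcome
    groups.
    """
    c = fixture.table.counts()
    groups = {g: [p for p in fixture.table.patients
                  if fixture.outcome[p] == g]
              for g in ("failure", "success")}
    out = {}
    for col, name in (("sim", "sim"), ("firm", "firm"),
                      ("sim_only", "latent")):
        entry = {}
        vals = {}
        for g, pats in groups.items():
            v = c.loc[pats, col].to_numpy()
            vals[g] = v
            med, q1, q3 = median_iqr(v, method)
            entry[g] = {"median": med, "iqr": [q1, q3], "n": int(v.size)}
        u, p = mann_whitney(vals["failure"], vals["success"], mode=mw_mode)
        entry["U"] = u
        entry["p"] = p
        out[name] = entry
    return out
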