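"""Statistical layer over harmonized tables and community matrices.

The scientific questions this supports:

* **Nutrient stoichiometry.**  Marine plankton draw down nitrate and
  phosphate in a roughly 16:1 molar ratio (the Redfield ratio), so an
  ordinary least-squares fit of phosphate on nitrate across harmonized
  ocean samples should recover a slope near 1/16 = 0.0625; freshwater
  samples are the expected outliers.
* **Environmental faceting.**  Physicochemical attributes summarized per
  (ENVO environmental feature x latitude climate zone) cell.
* **Community ordination.**  Taxon count matrices are filtered (shallow
  samples below a read-count threshold, contaminant taxa), normalized to
  relative abundance, turned into Bray-Curtis dissimilarities, and
  partitioned against a covariate (depth) by permutational distance-based
  redundancy analysis.  Per-taxon coefficients follow the adonis
  convention — each centered taxon abundance regressed on the centered
  covariate — so a positive coefficient means the taxon's relative
  abundance increases with depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix

from .errors import ColumnError, DegenerateInputError, ParameterError
from .harmonize import HarmonizedTable, climate_zone


@dataclass(frozen=True)
class RegressionResult:
    """Simple linear fit y = slope * x + intercept."""

    slope: float
    intercept: float
    r_squared: float
    n: int


def ols_fit(x, y) -> RegressionResult:
    """Closed-form ordinary least squares of ``y`` on ``x``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DegenerateInputError(
            f"length mismatch: x has {x.shape}, y has {y.shape}"
        )
    if x.ndim != 1 or x.size < 2:
        raise DegenerateInputError("need >= 2 paired observations")
    if np.isnan(x).any() or np.isnan(y).any():
        raise DegenerateInputError("inputs must not contain nulls")
    if np.ptp(x) == 0:
        raise DegenerateInputError("predictor is constant")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=int(x.size),
    )


def spearman(x, y) -> float:
    """Spearman rank correlation (Pearson on mean-ranked values)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise DegenerateInputError("need >= 3 paired observations")
    if np.isnan(x).any() or np.isnan(y).any():
        raise DegenerateInputError("inputs must not contain nulls")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("correlation undefined for a constant vector")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def facet_summary(
    table: HarmonizedTable,
    attribute: str,
    latitude_attr: str,
) -> pd.DataFrame:
    """Mean/sd/n of one attribute per (environmental feature, climate zone).

    Rows need a feature context term and a latitude value; cells with no
    observations are omitted, and sd is NaN for singleton cells.
    """
    if attribute not in table.values.columns:
        raise ColumnError(f"unknown attribute column {attribute!r}")
    if latitude_attr not in table.values.columns:
        raise ColumnError(f"unknown latitude column {latitude_attr!r}")
    if table.context is None or "feature" not in table.context:
        import warnings
        warnings.warn("table has no environmental context; empty summary")
        return pd.DataFrame(columns=["feature", "zone", "n", "mean", "sd"])

    rows = []
    vals = table.values[attribute]
    lats = table.values[latitude_attr]
    feats = table.context["feature"]
    mask = vals.notna() & lats.notna() & feats.notna()
    df = pd.DataFrame({
        "value": vals[mask],
        "feature": [f.curie if hasattr(f, "curie") else str(f)
                    for f in feats[mask]],
        "zone": [climate_zone(v).term.label for v in lats[mask]],
    })
    for (feature, zone), grp in df.groupby(["feature", "zone"], sort=True):
        rows.append({
            "feature": feature,
            "zone": zone,
            "n": len(grp),
            "mean": float(grp["value"].mean()),
            "sd": float(grp["value"].std(ddof=1)) if len(grp) > 1 else float("nan"),
        })
    return pd.DataFrame(rows, columns=["feature", "zone", "n", "mean", "sd"])


# ---------------------------------------------------------------------------
# community matrices

@dataclass
class CommunityMatrix:
    """Samples x taxa abundance matrix, as counts or relative abundances."""

    data: pd.DataFrame
    mode: str = "counts"  # or "relative"
    read_totals: pd.Series | None = None

    def __post_init__(self):
        if self.mode not in ("counts", "relative"):
            raise ParameterError(f"unknown mode {self.mode!r}")
        if (self.data.values < 0).any():
            raise ParameterError("abundances must be non-negative")
        if self.mode == "counts" and self.read_totals is None:
            self.read_totals = self.data.sum(axis=1)

    @property
    def samples(self) -> list:
        return list(self.data.index)

    @property
    def taxa(self) -> list:
        return list(self.data.columns)


def relative_abundance(
    counts: CommunityMatrix,
    min_reads: int = 100_000,
    contaminants: list[str] | None = None,
) -> CommunityMatrix:
    """Drop contaminant taxa, drop shallow samples, normalize rows.

    Contaminant columns are removed first; samples whose remaining total
    is below ``min_reads`` are dropped; surviving rows are divided by
    their totals so each sums to 1.
    """
    if counts.mode != "counts":
        raise ParameterError("relative_abundance expects a counts matrix")
    data = counts.data.drop(columns=list(contaminants or []), errors="ignore")
    totals = data.sum(axis=1)
    keep = totals >= min_reads
    if not keep.any():
        raise DegenerateInputError(
            f"all {len(totals)} samples fall below {min_reads} reads"
        )
    data = data.loc[keep]
    totals = totals.loc[keep]
    rel = data.div(totals, axis=0)
    return CommunityMatrix(rel, mode="relative", read_totals=totals)


def bray_curtis(m: CommunityMatrix) -> DistanceMatrix:
    """Bray-Curtis dissimilarity D[i,j] = sum|xi-xj| / sum(xi+xj)."""
    X = m.data.to_numpy(dtype=float)
    zero_rows = (X.sum(axis=1) == 0)
    if zero_rows.sum() >= 2:
        raise DegenerateInputError(
            "Bray-Curtis undefined between two all-zero samples"
        )
    from scipy.spatial.distance import pdist, squareform
    d = squareform(pdist(X, metric="braycurtis"))
    return DistanceMatrix(d, ids=[str(s) for s in m.samples])


# ---------------------------------------------------------------------------
# dbRDA

@dataclass
class DbRdaResult:
    """Permutational dbRDA of a distance matrix on one covariate."""

    coefficients: pd.Series
    r_squared: float
    pseudo_f: float
    p_value: float
    n_permutations: int
    seed: int
    n: int


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def dbrda(
    d,
    covariate,
    species: CommunityMatrix | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> DbRdaResult:
    """Partition distance-matrix variance on one continuous covariate.

    The distance matrix is Gower-centered (G = -1/2 J D^2 J); the model
    sum of squares is the projection of G onto the centered covariate,
    giving R^2 = x'Gx / (x'x tr G).  Significance comes from ``n_perm``
    random permutations of the covariate, with the (b+1)/(n_perm+1)
    p-value estimator so p is never zero.  Per-taxon coefficients are the
    least-squares slopes of each centered taxon column on the centered
    covariate (the adonis coefficient convention).
    """
    if isinstance(d, DistanceMatrix):
        dm = d.data
    else:
        dm = np.asarray(d, dtype=float)
    if dm.ndim != 2 or dm.shape[0] != dm.shape[1]:
        raise DegenerateInputError("distance matrix must be square")
    if not np.allclose(dm, dm.T, atol=1e-12):
        raise DegenerateInputError("distance matrix must be symmetric")
    x = np.asarray(covariate, dtype=float)
    n = dm.shape[0]
    if x.shape != (n,):
        raise DegenerateInputError(
            f"covariate length {x.shape} does not match {n} samples"
        )
    if np.ptp(x) == 0:
        raise DegenerateInputError("covariate is constant")
    if n_perm < 99:
        raise ParameterError("need at least 99 permutations")

    g = _gower_center(dm)
    xc = x - x.mean()
    ss_total = float(np.trace(g))
    xx = float(xc @ xc)

    def model_ss(xv: np.ndarray) -> float:
        return float(xv @ g @ xv) / xx  # tr(HG) with H = xv xv'/(xv'xv)

    ss_model = model_ss(xc)
    r2 = ss_model / ss_total
    df_resid = n - 2
    f_obs = (ss_model / 1.0) / ((ss_total - ss_model) / df_resid)

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        xp = xc[rng.permutation(n)]
        ss_p = model_ss(xp)
        f_p = (ss_p / 1.0) / ((ss_total - ss_p) / df_resid)
        if f_p >= f_obs:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)

    if species is not None:
        y = species.data.to_numpy(dtype=float)
        yc = y - y.mean(axis=0)
        coef = pd.Series(yc.T @ xc / xx, index=species.taxa, name="coefficient")
    else:
        coef = pd.Series(dtype=float, name="coefficient")

    return DbRdaResult(
        coefficients=coef,
        r_squared=float(r2),
        pseudo_f=float(f_obs),
        p_value=float(p),
        n_permutations=int(n_perm),
        seed=int(seed),
        n=int(n),
    )


def top_coefficients(r: DbRdaResult, k: int = 20) -> list[str]:
    """Taxa ordered by |coefficient| descending, ties broken by name."""
    if k < 1:
        raise ParameterError("k must be >= 1")
    ordered = sorted(r.coefficients.items(), key=lambda kv: (-abs(kv[1]), kv[0]))
    return [name for name, _ in ordered[:k]]
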