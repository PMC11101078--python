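"""Group statistics on isotopologue fractions and pathway-mixture deconvolution.

Group comparisons use Welch's unequal-variance t test (one- or two-tailed,
optionally paired) with a step-down Holm-Sidak adjustment applied within
per-metabolite families (all mass shifts of one metabolite form one family, as
in per-panel corrections; configurable).  Fractions are compared directly on
the simplex, without logit or arcsine transforms, matching how such data are
plotted and tested in practice.

Pathway contributions are inferred by constrained least squares: the observed
stacked fraction vector is approximated by a convex combination of the
regime template MIDs from the labeling engine, with nonnegative weights that
sum to one (sum-to-one imposed via an augmented constraint row, then exact
renormalization).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import t as t_dist

from .label_engine import MID, REGIMES

logger = logging.getLogger(__name__)

#: mass shifts whose fractions mark each PPP branch (combined Ru5P/R5P peak)
OXIDATIVE_MARKERS = (("Ru5P", 3), ("Ru5P", 5), ("S7P", 5))
NONOXIDATIVE_MARKERS = (("Ru5P", 2), ("S7P", 4))


@dataclass(frozen=True)
class GroupComparison:
    metabolite: str
    mass_shift: int
    mean_x: float
    mean_y: float
    t: float
    df: float
    p: float
    p_adjusted: float | None
    tails: int
    paired: bool


@dataclass(frozen=True)
class MarkerScore:
    oxidative: float
    nonoxidative: float


@dataclass(frozen=True)
class PathwayMixture:
    weights: dict[str, float]
    residual: float
    collinear: bool = False

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture weights must sum to 1, got {total}")
        if any(w < -1e-12 for w in self.weights.values()):
            raise ValueError("mixture weights must be nonnegative")


# --------------------------------------------------------------------------
# t tests
# --------------------------------------------------------------------------

def welch_t(
    x,
    y,
    tails: int = 2,
    metabolite: str = "",
    mass_shift: int = -1,
) -> GroupComparison:
    """Unpaired Welch t test with Satterthwaite degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise ValueError(
            "both samples have zero variance; the Welch statistic is undefined"
        )
    nx, ny = x.size, y.size
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = tails * t_dist.sf(abs(t), df)
    return GroupComparison(
        metabolite, mass_shift, float(x.mean()), float(y.mean()),
        float(t), float(df), float(min(p, 1.0)), None, tails, paired=False,
    )


def paired_t(
    x,
    y,
    tails: int = 2,
    metabolite: str = "",
    mass_shift: int = -1,
) -> GroupComparison:
    """Paired t test on within-pair differences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("paired samples must have equal size")
    if x.size < 2:
        raise ValueError("paired test needs at least 2 pairs")
    d = x - y
    vd = d.var(ddof=1)
    if vd == 0:
        raise ValueError("all pair differences identical; the t statistic is undefined")
    n = d.size
    t = d.mean() / np.sqrt(vd / n)
    df = float(n - 1)
    p = tails * t_dist.sf(abs(t), df)
    return GroupComparison(
        metabolite, mass_shift, float(x.mean()), float(y.mean()),
        float(t), df, float(min(p, 1.0)), None, tails, paired=True,
    )


# --------------------------------------------------------------------------
# multiple-testing adjustment
# --------------------------------------------------------------------------

def holm_sidak(pvalues, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Step-down Sidak adjustment; returns (adjusted p, reject flags).

    Sorted ascending, the i-th smallest p (0-based) is adjusted to
    ``1 - (1 - p)**(m - i)``; a running maximum enforces monotonicity and the
    result is mapped back to the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    return adjusted, adjusted <= alpha


# --------------------------------------------------------------------------
# group comparison tables
# --------------------------------------------------------------------------

def compare_groups(
    fractions: pd.DataFrame,
    group_x: str,
    group_y: str,
    value_column: str = "fraction",
    tails: int = 2,
    paired: bool = False,
    alpha: float = 0.05,
    family: str = "metabolite",
) -> pd.DataFrame:
    """Per-(metabolite, mass shift) t tests between two groups of samples.

    ``family`` controls the Holm-Sidak correction scope: ``"metabolite"``
    adjusts within each metabolite's mass shifts, ``"global"`` across all
    comparisons, ``"none"`` skips adjustment.
    """
    if family not in ("metabolite", "global", "none"):
        raise ValueError("family must be metabolite|global|none")
    test = paired_t if paired else welch_t
    rows: list[GroupComparison] = []
    for (met, shift), chunk in fractions.groupby(["metabolite", "mass_shift"], sort=True):
        x = chunk.loc[chunk["group"] == group_x, value_column].to_numpy()
        y = chunk.loc[chunk["group"] == group_y, value_column].to_numpy()
        if x.size < 2 or y.size < 2:
            continue
        try:
            rows.append(test(x, y, tails=tails, metabolite=met, mass_shift=int(shift)))
        except ValueError as err:  # degenerate block (e.g. all-zero fractions)
            logger.info("skipping %s m+%d: %s", met, shift, err)
    out = pd.DataFrame([vars(r) for r in rows])
    if out.empty:
        return out
    if family == "none":
        out["p_adjusted"] = out["p"]
        out["reject"] = out["p"] <= alpha
    elif family == "global":
        out["p_adjusted"], out["reject"] = holm_sidak(out["p"].to_numpy(), alpha)
    else:
        for met, idx in out.groupby("metabolite").groups.items():
            adj, rej = holm_sidak(out.loc[idx, "p"].to_numpy(), alpha)
            out.loc[idx, "p_adjusted"] = adj
            out.loc[idx, "reject"] = rej
        out["reject"] = out["reject"].astype(bool)
    return out


# --------------------------------------------------------------------------
# marker scores and mixture fitting
# --------------------------------------------------------------------------

def marker_scores(mids: dict[str, MID]) -> MarkerScore:
    """Sum the diagnostic isotopologue fractions for each PPP branch.

    Oxidative/cyclic activity shows in Ru5P m+3, Ru5P m+5 and S7P m+5;
    nonoxidative activity in Ru5P m+2 and S7P m+4.
    """
    for met in ("Ru5P", "S7P"):
        if met not in mids:
            raise ValueError(f"marker scores need an MID for {met}")
    ox = sum(mids[met][shift] for met, shift in OXIDATIVE_MARKERS)
    nonox = sum(mids[met][shift] for met, shift in NONOXIDATIVE_MARKERS)
    return MarkerScore(float(ox), float(nonox))


def fit_mixture(
    observed: dict[str, MID] | pd.Series,
    templates: pd.DataFrame,
    sum_weight: float = 1e3,
) -> PathwayMixture:
    """Nonnegative least-squares deconvolution of observed MIDs into regime weights.

    ``templates`` is the (metabolite, mass_shift)-indexed matrix from
    :func:`pentrace.label_engine.template_mids`; ``observed`` either a mapping
    metabolite -> MID covering the template metabolites, or a Series on the
    same index.  The sum-to-one constraint enters as an augmented row with
    weight ``sum_weight``; weights are renormalized exactly afterwards.
    """
    if templates.shape[1] < 2:
        raise ValueError("mixture fitting needs at least 2 regime templates")
    if isinstance(observed, pd.Series):
        b = observed.reindex(templates.index)
        if b.isna().any():
            missing = templates.index[b.isna()].tolist()
            raise ValueError(f"observed vector is missing entries for {missing[:4]}")
        b = b.to_numpy(dtype=float)
    else:
        vals = []
        for met, shift in templates.index:
            if met not in observed:
                raise ValueError(f"observed MIDs are missing metabolite {met!r}")
            vals.append(observed[met][shift])
        b = np.asarray(vals, dtype=float)

    a = templates.to_numpy(dtype=float)
    collinear = bool(np.linalg.matrix_rank(a, tol=1e-10) < a.shape[1])
    if collinear:
        logger.warning("regime templates are collinear; mixture weights not unique")

    a_aug = np.vstack([a, sum_weight * np.ones(a.shape[1])])
    b_aug = np.concatenate([b, [sum_weight]])
    w, _ = nnls(a_aug, b_aug)
    if w.sum() <= 0:
        raise ValueError("mixture fit returned all-zero weights")
    w = w / w.sum()
    residual = float(np.linalg.norm(a @ w - b))
    weights = {regime: float(wi) for regime, wi in zip(templates.columns, w)}
    return PathwayMixture(weights, residual, collinear)


def default_regimes() -> tuple[str, ...]:
    return REGIMES
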