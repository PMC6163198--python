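"""Two-group differential expression with empirical-Bayes variance moderation.

The model is the classical hierarchical one for per-probe variances on a
log2-expression matrix: the residual variance s_g^2 of probe g (pooled over
the two groups, d_g = n1 + n2 - 2 df) is treated as scaled chi-square around
a latent sigma_g^2, and sigma_g^2 itself follows a scaled inverse chi-square
prior with d0 degrees of freedom and scale s0^2.  The posterior variance

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

shrinks noisy per-probe variances toward the prior scale, and the moderated
statistic t_g = logFC_g / sqrt(s~_g^2 * (1/n1 + 1/n2)) is referred to a t
distribution on d0 + d_g degrees of freedom.  (d0, s0^2) are estimated by
moment-matching the empirical distribution of log s_g^2 across probes.

logFC is oriented tumor-minus-normal: mean(HGSOC) - mean(FTE), in log2 units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("cilioprior")

GROUPS = ("FTE", "HGSOC")


@dataclass
class ExpressionDataset:
    """A log2-scale probes x samples matrix with per-sample group labels."""

    matrix: pd.DataFrame
    groups: pd.Series  # indexed by sample id, values in {"FTE", "HGSOC"}
    name: str = ""

    def __post_init__(self):
        bad = set(self.groups.unique()) - set(GROUPS)
        if bad:
            raise ValueError(f"{self.name}: unknown group label(s) {sorted(bad)}")
        for g in GROUPS:
            n = int((self.groups == g).sum())
            if n < 2:
                raise ValueError(f"{self.name}: group {g} has {n} samples, need >= 2")
        if not np.isfinite(self.matrix.to_numpy()).all():
            raise ValueError(f"{self.name}: non-finite expression values")

    @property
    def n_fte(self) -> int:
        return int((self.groups == "FTE").sum())

    @property
    def n_hgsoc(self) -> int:
        return int((self.groups == "HGSOC").sum())


@dataclass(frozen=True)
class DeThresholds:
    """Significance cut-offs; both inequalities are strict."""

    alpha_q: float = 0.05
    min_abs_logfc: float = 1.0

    def __post_init__(self):
        if not 0 < self.alpha_q < 1:
            raise ValueError("alpha_q must be in (0, 1)")
        if self.min_abs_logfc < 0:
            raise ValueError("min_abs_logfc must be >= 0")


def trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration.

    trigamma is strictly decreasing and convex on (0, inf); the iteration on
    1/y converges monotonically from the closed-form start y0 = 0.5 + 1/x.
    """
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Moment-match (d0, s0^2) from per-probe sample variances.

    Works on z = log(s2): under the model, Var(z) = trigamma(df/2) +
    trigamma(d0/2) and E[z] = log(s0^2) + [digamma(df/2) - log(df/2)] -
    [digamma(d0/2) - log(d0/2)].  If the observed spread does not exceed the
    chi-square sampling noise (underdispersed variances), d0 is infinite and
    every probe shrinks fully to s0^2.
    """
    if len(s2) < 2:
        raise ValueError(
            "need >= 2 probes to estimate the variance prior; use plain-t mode instead"
        )
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(emean))
    return d0, s0_sq


class ModeratedTTest:
    """Empirical-Bayes moderated two-sample t model for one expression dataset.

    Parameters
    ----------
    dataset
        Log2-scale expression with FTE / HGSOC sample labels.
    shrink
        When False the prior is dropped (d0 = 0) and the statistic reduces to
        the pooled-variance two-sample t — the sensitivity-analysis mode.

    Examples
    --------
    >>> results = ModeratedTTest(dataset).fit()
    >>> results.table.head()        # logFC, t, p, q per probe
    >>> print(results.summary())
    """

    def __init__(self, dataset: ExpressionDataset, shrink: bool = True):
        self.dataset = dataset
        self.shrink = shrink

    def fit(self) -> "ModeratedTTestResults":
        ds = self.dataset
        mask_f = (ds.groups == "FTE").to_numpy()
        mask_h = (ds.groups == "HGSOC").to_numpy()
        x = ds.matrix.to_numpy(dtype=float)
        n1, n2 = int(mask_f.sum()), int(mask_h.sum())
        d_g = n1 + n2 - 2

        mean_f = x[:, mask_f].mean(axis=1)
        mean_h = x[:, mask_h].mean(axis=1)
        logfc = mean_h - mean_f
        ss = x[:, mask_f].var(axis=1, ddof=1) * (n1 - 1) + x[:, mask_h].var(axis=1, ddof=1) * (n2 - 1)
        s2 = ss / d_g

        keep = s2 > 0
        excluded = list(ds.matrix.index[~keep])
        if excluded:
            logger.info("%s: excluded %d zero-variance probe(s)", ds.name, len(excluded))
        probes = ds.matrix.index[keep]
        logfc, s2 = logfc[keep], s2[keep]

        if self.shrink:
            d0, s0_sq = estimate_variance_prior(s2, d_g)
        else:
            d0, s0_sq = 0.0, float(np.median(s2))
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0_sq)
            df_total = np.inf
        else:
            s2_post = (d0 * s0_sq + d_g * s2) / (d0 + d_g)
            df_total = d0 + d_g

        se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
        tstat = logfc / se
        if np.isinf(df_total):
            p = 2.0 * stats.norm.sf(np.abs(tstat))
        else:
            p = 2.0 * stats.t.sf(np.abs(tstat), df=df_total)

        table = pd.DataFrame(
            {"logFC": logfc, "s2": s2, "s2_post": s2_post, "t": tstat, "p": p},
            index=pd.Index(probes, name="probe_id"),
        )
        table["q"] = bh_adjust(table["p"].to_numpy())
        return ModeratedTTestResults(
            model=self, table=table, d0=d0, s0_sq=s0_sq, d_g=d_g,
            n1=n1, n2=n2, excluded_probes=excluded,
        )


@dataclass
class ModeratedTTestResults:
    """Per-probe effects and moderated statistics with the fitted prior."""

    model: ModeratedTTest
    table: pd.DataFrame  # logFC, s2, s2_post, t, p, q per probe
    d0: float
    s0_sq: float
    d_g: int
    n1: int
    n2: int
    excluded_probes: list

    @property
    def df_total(self) -> float:
        return self.d0 + self.d_g

    def significant(self, thresholds: DeThresholds = DeThresholds()) -> pd.DataFrame:
        return apply_thresholds(self.table, thresholds)

    def summary(self, top: int = 10) -> str:
        ds = self.model.dataset
        lines = [
            "Moderated two-sample t-test (empirical-Bayes variance shrinkage)",
            "=" * 64,
            f"Dataset: {ds.name or '<unnamed>'}   "
            f"probes: {len(self.table)}  FTE: {self.n1}  HGSOC: {self.n2}",
            f"Prior df (d0): {self.d0:.4g}   prior variance (s0^2): {self.s0_sq:.4g}",
            f"Residual df per probe: {self.d_g}   total df: {self.df_total:.4g}",
            f"Excluded zero-variance probes: {len(self.excluded_probes)}",
            "",
            f"Top {top} probes by adjusted p-value (logFC = log2 HGSOC - FTE):",
        ]
        cols = ["logFC", "t", "p", "q"]
        lines.append(self.table.sort_values("q")[cols].head(top).to_string(
            float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)


def fit_moderated_t(ds: ExpressionDataset, shrink: bool = True) -> ModeratedTTestResults:
    """Functional wrapper over :class:`ModeratedTTest`."""
    return ModeratedTTest(ds, shrink=shrink).fit()


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order, capped
    at 1 and monotone along the sorted p sequence."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def apply_thresholds(table: pd.DataFrame, th: DeThresholds = DeThresholds()) -> pd.DataFrame:
    """Retain probes with q < alpha_q and |logFC| > min_abs_logfc (both
    strict) and attach the direction sign (+1 up in HGSOC, -1 down)."""
    if "q" not in table.columns:
        raise ValueError("adjusted p-values (q) must be populated before thresholding")
    keep = (table["q"] < th.alpha_q) & (table["logFC"].abs() > th.min_abs_logfc)
    out = table.loc[keep].copy()
    out["direction"] = np.sign(out["logFC"]).astype(int)
    return out


def concordant_probes(sig_a: pd.DataFrame, sig_b: pd.DataFrame) -> pd.DataFrame:
    """Intersect two significant-probe tables on probe id, keeping only
    probes whose direction of change agrees.

    Returns a frame indexed by probe with per-dataset logFC and q
    (suffixes _a / _b) plus the shared direction.
    """
    merged = sig_a[["logFC", "q", "direction"]].join(
        sig_b[["logFC", "q", "direction"]], how="inner", lsuffix="_a", rsuffix="_b"
    )
    merged = merged.loc[merged["direction_a"] == merged["direction_b"]].copy()
    merged["direction"] = merged["direction_a"]
    return merged.drop(columns=["direction_a", "direction_b"])
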