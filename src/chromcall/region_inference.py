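"""Per-region statistical testing and scoring.

Each region's observed fragment-midpoint count y is tested against its
locally adjusted expected background lambda_t with a one-sided Negative
Binomial tail test, p = P(Y >= y | Y ~ NB(mu=lambda_t, size=theta)),
using the experiment's global dispersion theta (the Poisson tail when
theta is infinite).  P-values are Benjamini-Hochberg adjusted across all
non-blacklisted regions.  Two complementary effect measures are reported:

* enrichment score  s = log2((y + eps) / (lambda_t + eps))   (log2 units)
* z-score           z = (y - lambda_t) / sqrt(lambda_t + lambda_t^2/theta)

A region is called "present" (1) when s > score_min AND padj < fdr_max
(both strict; defaults 1.5 and 0.25); blacklisted regions carry NA.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .background_model import (
    BackgroundModel,
    compute_modulation,
    expected_signal,
    fit_background,
)
from .fragment_counts import MidpointTrack, count_midpoints
from .genome_io import GenomeTiling, RegionSet

logger = logging.getLogger(__name__)

__all__ = [
    "CallConfig",
    "nb_tail_pvalue",
    "nb_tail_pvalues",
    "bh_adjust",
    "enrichment_score",
    "z_score",
    "call_presence",
    "run_sample",
    "write_calls_tsv",
    "read_calls_tsv",
]

#: Columns of a region-call table, in output order.
CALL_COLUMNS = [
    "chrom", "start", "end", "name", "y", "y_ctrl", "m", "lambda_t",
    "p", "padj", "score", "z", "call",
]


@dataclass
class CallConfig:
    """Tunable parameters for presence calling.

    epsilon: pseudo-count in the log2 enrichment score (keeps s(0,0)=0).
    score_min / fdr_max: presence thresholds, strict inequalities.
    """

    epsilon: float = 1.0
    score_min: float = 1.5
    fdr_max: float = 0.25

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if not (math.isfinite(self.score_min) and math.isfinite(self.fdr_max)):
            raise ValueError("thresholds must be finite")


def nb_tail_pvalues(
    y: np.ndarray, lambda_t: np.ndarray, theta: float
) -> np.ndarray:
    """Vectorised one-sided tail p = P(Y >= y) under NB(mu, size=theta).

    Computed as the survival function at y-1 for numerical accuracy.
    theta = inf uses the Poisson tail.  Degenerate inputs: y = 0 gives
    p = 1 (the whole support); lambda_t = 0 with y > 0 gives p = 0.
    """
    y = np.asarray(y)
    lambda_t = np.asarray(lambda_t, dtype=float)
    if np.any(y < 0) or np.any(lambda_t < 0):
        raise ValueError("y and lambda_t must be non-negative")
    if not (theta > 0):
        raise ValueError("theta must be positive or infinite")
    y, lambda_t = np.broadcast_arrays(y, lambda_t)
    p = np.empty(y.shape, dtype=float)
    zero_mu = lambda_t == 0
    p[zero_mu] = np.where(y[zero_mu] > 0, 0.0, 1.0)
    ok = ~zero_mu
    if np.any(ok):
        if math.isinf(theta):
            p[ok] = stats.poisson.sf(y[ok] - 1, lambda_t[ok])
        else:
            nb_p = theta / (theta + lambda_t[ok])
            p[ok] = stats.nbinom.sf(y[ok] - 1, theta, nb_p)
    return p


def nb_tail_pvalue(y: int, lambda_t: float, theta: float) -> float:
    """Scalar convenience wrapper around :func:`nb_tail_pvalues`."""
    return float(nb_tail_pvalues(np.array([y]), np.array([lambda_t]), theta)[0])


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Callers exclude blacklisted regions before adjustment (their adjusted
    value is NA in the call table).
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrichment_score(
    y: np.ndarray | float, lambda_t: np.ndarray | float, epsilon: float = 1.0
) -> np.ndarray | float:
    """log2 ratio of observed to expected counts with pseudo-count epsilon."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    return np.log2((np.asarray(y, dtype=float) + epsilon)
                   / (np.asarray(lambda_t, dtype=float) + epsilon))


def z_score(
    y: np.ndarray | float, lambda_t: np.ndarray | float, theta: float
) -> np.ndarray | float:
    """Standardised deviation under the NB mean-variance relation.

    z = (y - lambda_t)/sqrt(lambda_t + lambda_t^2/theta); the denominator
    reduces to sqrt(lambda_t) in the Poisson limit.  NaN when lambda_t = 0.
    """
    y = np.asarray(y, dtype=float)
    lambda_t = np.asarray(lambda_t, dtype=float)
    var = lambda_t if math.isinf(theta) else lambda_t + lambda_t**2 / theta
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(lambda_t > 0, (y - lambda_t) / np.sqrt(var), np.nan)
    return z if z.ndim else float(z)


def call_presence(
    score: float,
    padj: float,
    blacklisted: bool = False,
    score_min: float = 1.5,
    fdr_max: float = 0.25,
):
    """Binary presence status: 1 iff score > score_min and padj < fdr_max.

    Strict inequalities.  Blacklisted regions get NA (pandas missing).
    """
    if blacklisted:
        return pd.NA
    return 1 if (score > score_min and padj < fdr_max) else 0


def run_sample(
    experiment_track: MidpointTrack,
    control_track: MidpointTrack | None,
    regions: RegionSet,
    tiling: GenomeTiling,
    config: CallConfig | None = None,
) -> pd.DataFrame:
    """Full single-sample inference: counts -> background -> test -> calls.

    Fits the background separately for the experiment and (when supplied)
    the control on the same genome tiling, derives the per-region
    modulation and expected signal, and returns a table aligned to the
    region order with columns ``CALL_COLUMNS``.  Blacklisted regions keep
    their counts but carry NA statistics and call.
    """
    if config is None:
        config = CallConfig()
    exp_chroms = set(experiment_track.midpoints)
    region_chroms = {iv.chrom for iv in regions.regions}
    if exp_chroms and not (region_chroms & exp_chroms):
        logger.warning(
            "experiment track and regions share no chromosome; counts are zero"
        )

    y = count_midpoints(experiment_track, regions.regions)
    exp_tiles = count_midpoints(experiment_track, tiling.tiles)
    model = fit_background(
        exp_tiles, tiling.tile_width, source=experiment_track.source
    )

    if control_track is not None:
        y_ctrl = count_midpoints(control_track, regions.regions)
        ctrl_tiles = count_midpoints(control_track, tiling.tiles)
        lambda_g_ctrl = float(np.asarray(ctrl_tiles).mean()) if ctrl_tiles.size else 0.0
        if lambda_g_ctrl == 0.0:
            raise ValueError("control background rate is zero; modulation undefined")
        m = compute_modulation(y_ctrl, lambda_g_ctrl)
    else:
        y_ctrl = None
        m = compute_modulation(None, None, n_regions=len(regions))

    lam_t = expected_signal(m, model)
    black = regions.blacklisted
    testable = ~black

    p = np.full(len(regions), np.nan)
    p[testable] = nb_tail_pvalues(y[testable], lam_t[testable], model.theta)
    padj = np.full(len(regions), np.nan)
    if testable.any():
        padj[testable] = bh_adjust(p[testable])
    score = np.where(
        testable, enrichment_score(y, lam_t, config.epsilon), np.nan
    )
    z = np.where(testable, z_score(y, lam_t, model.theta), np.nan)

    call = pd.array(
        [
            call_presence(
                score[i], padj[i], bool(black[i]),
                config.score_min, config.fdr_max,
            )
            for i in range(len(regions))
        ],
        dtype="Int64",
    )

    table = pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in regions.regions],
            "start": [iv.start for iv in regions.regions],
            "end": [iv.end for iv in regions.regions],
            "name": regions.names,
            "y": y,
            "y_ctrl": (
                pd.array(y_ctrl, dtype="Int64")
                if y_ctrl is not None
                else pd.array([pd.NA] * len(regions), dtype="Int64")
            ),
            "m": m,
            "lambda_t": lam_t,
            "p": p,
            "padj": padj,
            "score": score,
            "z": z,
            "call": call,
        }
    )
    table.attrs["background_model"] = model
    return table


def _fmt(x) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)) or x is pd.NA:
        return "NA"
    if isinstance(x, (float, np.floating)):
        return f"{x:.6g}"
    return str(x)


def write_calls_tsv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a call table as TSV (first three columns BED-compatible).

    Floats are printed at 6 significant digits; missing values as "NA".
    """
    cols = [c for c in CALL_COLUMNS if c in table.columns]
    if "expression" in table.columns:
        cols.append("expression")
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for _, row in table[cols].iterrows():
            fh.write("\t".join(_fmt(row[c]) for c in cols) + "\n")


def read_calls_tsv(path: str | Path) -> pd.DataFrame:
    """Read a call table written by :func:`write_calls_tsv`."""
    table = pd.read_csv(path, sep="\t", na_values=["NA"])
    if "call" in table.columns:
        table["call"] = table["call"].astype("Int64")
    if "y_ctrl" in table.columns:
        table["y_ctrl"] = table["y_ctrl"].astype("Int64")
    return table
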