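"""Global Negative Binomial background and control-based local modulation.

Counts in genome-wide tiles are modelled as Negative Binomial with mean
``lambda_g`` (the genome-wide background rate) and size parameter
``theta`` (global dispersion), both estimated once per experiment from
all non-blacklisted tiles.  Var = mu + mu^2/theta; theta -> infinity
recovers Poisson.  A matched control, when present, modulates the global
rate per region: m_i = max(1, y_i(ctrl)/lambda_g(ctrl)), and the expected
signal is lambda_t,i = m_i * lambda_g.  The lower bound of one prevents
deflation of the expected background in regions with low control signal;
without a control m_i = 1 everywhere and inference is against the global
background alone.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "INFINITE",
    "BackgroundModel",
    "estimate_lambda_g",
    "estimate_dispersion",
    "fit_background",
    "compute_modulation",
    "expected_signal",
]

#: Distinguished dispersion value meaning "Poisson" (no overdispersion).
INFINITE = math.inf

# Method-of-moments theta above this is numerically indistinguishable from
# Poisson and is clamped, keeping NB tail computations stable.
_THETA_CLAMP = 1e6


@dataclass
class BackgroundModel:
    """Fitted global null for one experiment: (lambda_g, theta, tiling info)."""

    lambda_g: float
    theta: float  # > 0, or INFINITE for the Poisson limit
    tile_width: int
    n_tiles: int
    source: str = ""

    @property
    def is_poisson(self) -> bool:
        return math.isinf(self.theta)

    def to_json(self, path: str | Path) -> None:
        """Serialize as a small JSON sidecar for provenance."""
        payload = {
            "lambda_g": self.lambda_g,
            "theta": "inf" if self.is_poisson else self.theta,
            "tile_width": self.tile_width,
            "n_tiles": self.n_tiles,
            "source": self.source,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "BackgroundModel":
        payload = json.loads(Path(path).read_text())
        theta = payload["theta"]
        return cls(
            lambda_g=float(payload["lambda_g"]),
            theta=INFINITE if theta == "inf" else float(theta),
            tile_width=int(payload["tile_width"]),
            n_tiles=int(payload["n_tiles"]),
            source=payload.get("source", ""),
        )


def estimate_lambda_g(tile_counts: np.ndarray, role: str = "treatment") -> float:
    """Mean count per non-blacklisted tile, zero-count tiles included.

    Retaining zero tiles avoids upward bias in sparse data: lambda_g must
    reflect the overall sequencing background, not local enrichment.  A
    zero mean is an error for a control (it would divide the modulation)
    and a warning for a treatment.
    """
    tile_counts = np.asarray(tile_counts)
    if tile_counts.size == 0:
        raise ValueError("cannot estimate lambda_g from zero tiles")
    lam = float(tile_counts.mean())
    if lam == 0.0:
        if role == "control":
            raise ValueError(
                "control background rate is zero; modulation undefined"
            )
        logger.warning("treatment background rate is zero (empty experiment?)")
    return lam


def estimate_dispersion(tile_counts: np.ndarray) -> float:
    """Method-of-moments NB size estimate theta = mu^2 / (s^2 - mu).

    Uses the unbiased (n-1) sample variance.  When s^2 <= mu the data show
    no overdispersion and INFINITE (the Poisson limit) is returned; very
    large finite estimates (> 1e6) are clamped to INFINITE for numerical
    stability of the NB tail.
    """
    tile_counts = np.asarray(tile_counts, dtype=float)
    if tile_counts.size < 2:
        raise ValueError("need at least 2 tiles to estimate dispersion")
    mu = tile_counts.mean()
    s2 = tile_counts.var(ddof=1)
    if s2 <= mu or mu == 0.0:
        return INFINITE
    theta = mu * mu / (s2 - mu)
    return INFINITE if theta > _THETA_CLAMP else float(theta)


def fit_background(
    tile_counts: np.ndarray,
    tile_width: int,
    source: str = "",
    role: str = "treatment",
) -> BackgroundModel:
    """Fit (lambda_g, theta) from non-blacklisted tile counts."""
    tile_counts = np.asarray(tile_counts)
    return BackgroundModel(
        lambda_g=estimate_lambda_g(tile_counts, role=role),
        theta=estimate_dispersion(tile_counts),
        tile_width=tile_width,
        n_tiles=int(tile_counts.size),
        source=source,
    )


def compute_modulation(
    control_counts: np.ndarray | None,
    lambda_g_ctrl: float | None,
    n_regions: int | None = None,
) -> np.ndarray:
    """Per-region modulation m_i = max(1, y_i(ctrl)/lambda_g(ctrl)).

    Without a control all m_i = 1 (``n_regions`` then sizes the output).
    """
    if control_counts is None:
        if n_regions is None:
            raise ValueError("n_regions required when no control is given")
        return np.ones(n_regions)
    if lambda_g_ctrl is None or lambda_g_ctrl <= 0:
        raise ValueError("control provided but its lambda_g is not positive")
    control_counts = np.asarray(control_counts, dtype=float)
    return np.maximum(1.0, control_counts / lambda_g_ctrl)


def expected_signal(m: np.ndarray, model: BackgroundModel) -> np.ndarray:
    """Locally adjusted expected background lambda_t,i = m_i * lambda_g."""
    return np.asarray(m, dtype=float) * model.lambda_g
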