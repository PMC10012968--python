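"""Acinar perfusion summary metrics.

Headline outputs of a converged run: the gravitational gradient of
perfusion G (%/cm, ordinary least-squares slope of mean-normalized acinar
flow against gravitational height, positive when the dependent lung
receives more flow), the coefficient of variation COV (%), left/right lung
flow splits (%), and the standard deviation of normalized flow per height
bin.  Sample (n-1) standard deviations are used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def normalized_flow(flows) -> np.ndarray:
    """Acinar flow as percent of the mean (mean = 100 %)."""
    q = np.asarray(flows, float)
    m = q.mean()
    if m <= 0:
        raise ValueError("mean acinar flow must be positive")
    return 100.0 * q / m


def gravitational_gradient(flows, heights_cm, gravity_on: bool = True):
    """OLS slope of normalized flow (%) vs gravitational height (cm).

    Heights increase away from the dependent (lowest) lung; a negative raw
    slope therefore means more flow in dependent regions, and the returned
    G flips the sign so that positive G = dependent-favoring gradient.
    Returns ``None`` for zero-gravity input, where the quantity is
    undefined.
    """
    if not gravity_on:
        return None
    h = np.asarray(heights_cm, float)
    if len(np.unique(h)) < 2:
        raise ValueError("need at least two distinct heights")
    nf = normalized_flow(flows)
    slope = np.polyfit(h, nf, 1)[0]
    return float(-slope)


def coefficient_of_variation(flows) -> float:
    """100 * sample SD / mean over acini (%)."""
    q = np.asarray(flows, float)
    if q.size == 0:
        raise ValueError("empty flow array")
    m = q.mean()
    if m <= 0:
        raise ValueError("mean acinar flow must be positive")
    if q.size == 1:
        return 0.0
    return float(100.0 * q.std(ddof=1) / m)


def lung_flow_split(flows, lungs) -> dict:
    """Percent of total flow per lung; fractions sum to 100."""
    q = np.asarray(flows, float)
    labels = np.asarray(lungs)
    if len(q) != len(labels):
        raise ValueError("flows and lung labels differ in length")
    if any(l not in ("left", "right") for l in np.unique(labels)):
        raise ValueError("every acinus must be labeled 'left' or 'right'")
    total = q.sum()
    if total <= 0:
        raise ValueError("total flow must be positive")
    return {side: float(100.0 * q[labels == side].sum() / total)
            for side in ("left", "right")}


def sd_height_profile(flows, heights_cm, n_bins: int = 10):
    """Sample SD of normalized flow in equal-width height bins.

    Returns ``(bin_centers_cm, sd_per_bin)``; bins holding fewer than two
    acini report NaN.
    """
    if n_bins < 2:
        raise ValueError("need at least two bins")
    h = np.asarray(heights_cm, float)
    nf = normalized_flow(flows)
    edges = np.linspace(h.min(), h.max(), n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    idx = np.clip(np.digitize(h, edges) - 1, 0, n_bins - 1)
    sd = np.full(n_bins, np.nan)
    for b in range(n_bins):
        vals = nf[idx == b]
        if len(vals) >= 2:
            sd[b] = vals.std(ddof=1)
    return centers, sd


def sd_profile_difference(profile_a, profile_b):
    """Bin-wise difference of two SD-vs-height profiles (a minus b).

    Both must come from :func:`sd_height_profile` with the same bin count;
    bins missing in either profile are NaN in the difference.
    """
    ca, sa = profile_a
    cb, sb = profile_b
    if len(sa) != len(sb):
        raise ValueError("profiles have different bin counts")
    return ca, sa - sb


@dataclass
class PerfusionSummary:
    """Per-acinus flows with heights and the derived aggregate metrics."""

    flows: np.ndarray  # m^3/s
    heights_cm: np.ndarray  # 0 at the most dependent acinus
    lungs: np.ndarray  # "left" | "right"
    posture: str
    gravity_on: bool

    @classmethod
    def from_state(cls, network, state, posture) -> "PerfusionSummary":
        return cls(flows=np.asarray(state.acinar_flow, float),
                   heights_cm=np.asarray(state.acinar_height, float) * 100.0,
                   lungs=np.asarray(network.acinus_lung),
                   posture=posture.name,
                   gravity_on=posture.g > 0.0)

    @property
    def normalized(self) -> np.ndarray:
        return normalized_flow(self.flows)

    def gradient(self):
        return gravitational_gradient(self.flows, self.heights_cm,
                                      gravity_on=self.gravity_on)

    def cov(self) -> float:
        return coefficient_of_variation(self.flows)

    def split(self) -> dict:
        return lung_flow_split(self.flows, self.lungs)

    def sd_profile(self, n_bins: int = 10):
        return sd_height_profile(self.flows, self.heights_cm, n_bins)

    def metrics_dict(self, cardiac_output_L_min: float | None = None) -> dict:
        g = self.gradient()
        split = self.split()
        return {
            "posture": self.posture,
            "CO_L_min": cardiac_output_L_min,
            "G_percent_per_cm": g,
            "COV_percent": self.cov(),
            "right_fraction_percent": split["right"],
            "left_fraction_percent": split["left"],
        }
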