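"""Selection / drift / mixed verdicts from posterior slope summaries.

The decision rule reads the signs of the daily slopes of the replicate
similarity distribution: selection is called when the mean similarity is
non-decreasing and its standard deviation shrinking (replicates converge,
spread tightens); drift when the mean decreases and the spread grows
(replicates diverge); anything else is a mix of the two processes.  The
sigma slope enters only through its sign, which is invariant to the
(monotone) link the model used for sigma.

Labels are assigned from posterior means, matching how slope estimates are
plotted in quadrant space; ``quadrant_probabilities`` adds an
uncertainty-aware complement, the posterior mass in each sign quadrant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import ValidationError
from .model import GroupSlopes

LABELS = ("selection", "drift", "mixed")
QUADRANTS = ("selection", "drift", "mu_up_sigma_up", "mu_down_sigma_down")


def classify_assembly(delta_mu: float, delta_sigma: float) -> str:
    """Point-estimate quadrant rule.

    selection iff delta_mu >= 0 and delta_sigma < 0; drift iff delta_mu < 0
    and delta_sigma > 0; mixed otherwise (the boundary delta_sigma == 0 is
    mixed: the strict inequality of the sigma criterion is applied).
    """
    if not (math.isfinite(delta_mu) and math.isfinite(delta_sigma)):
        raise ValidationError(f"slopes must be finite, got ({delta_mu}, {delta_sigma})")
    if delta_mu >= 0 and delta_sigma < 0:
        return "selection"
    if delta_mu < 0 and delta_sigma > 0:
        return "drift"
    return "mixed"


def quadrant_probabilities(delta_mu_draws: np.ndarray,
                           delta_sigma_draws: np.ndarray) -> dict[str, float]:
    """Posterior mass in each (sign delta_mu, sign delta_sigma) quadrant.

    Cells: selection = (>= 0, < 0); drift = (< 0, >= 0); the two remaining
    quadrants are reported separately. Probabilities sum to 1.
    """
    mu = np.asarray(delta_mu_draws, dtype=float)
    sg = np.asarray(delta_sigma_draws, dtype=float)
    if mu.shape != sg.shape or mu.ndim != 1 or mu.size == 0:
        raise ValidationError("draws must be paired non-empty 1-D arrays of equal length")
    if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(sg))):
        raise ValidationError("draws must be finite")
    n = mu.size
    probs = {
        "selection": float(np.sum((mu >= 0) & (sg < 0)) / n),
        "drift": float(np.sum((mu < 0) & (sg >= 0)) / n),
        "mu_up_sigma_up": float(np.sum((mu >= 0) & (sg >= 0)) / n),
        "mu_down_sigma_down": float(np.sum((mu < 0) & (sg < 0)) / n),
    }
    assert abs(sum(probs.values()) - 1.0) < 1e-9
    return probs


@dataclass
class AssemblyCall:
    """One group's verdict with the slope summaries behind it."""

    group: str
    delta_mu_mean: float
    delta_mu_sd: float
    delta_sigma_mean: float
    delta_sigma_sd: float
    label: str
    quadrants: dict[str, float]


def make_assembly_calls(slopes: GroupSlopes) -> pd.DataFrame:
    """Verdict per mean-model group, pairing each (disturbance, capacity)
    mean slope with the sigma slope of its disturbance level, draw by draw."""
    rows = []
    for group, mu_draws in slopes.mu_slopes.items():
        d_level = group[0] if group and group[0] in "UD" else None
        sigma_draws = None
        if slopes.sigma_slopes:
            sigma_draws = slopes.sigma_slopes.get(d_level, None)
            if sigma_draws is None and len(slopes.sigma_slopes) == 1:
                sigma_draws = next(iter(slopes.sigma_slopes.values()))
        if sigma_draws is None:
            raise ValidationError(
                f"no sigma slope available for group {group!r}; the sigma model "
                "has no time term")
        mu_mean, sg_mean = float(mu_draws.mean()), float(sigma_draws.mean())
        probs = quadrant_probabilities(mu_draws, sigma_draws)
        rows.append({
            "group": group, "period": slopes.period, "index": slopes.index,
            "delta_mu_mean": mu_mean, "delta_mu_sd": float(mu_draws.std(ddof=1)),
            "delta_sigma_mean": sg_mean,
            "delta_sigma_sd": float(sigma_draws.std(ddof=1)),
            "label": classify_assembly(mu_mean, sg_mean),
            "p_selection": probs["selection"], "p_drift": probs["drift"],
            "p_other_quadrants": probs["mu_up_sigma_up"] + probs["mu_down_sigma_down"],
        })
    return pd.DataFrame(rows)


def format_report(calls: pd.DataFrame) -> str:
    """Plain-text block summarising the assembly calls."""
    lines = ["Community assembly calls", "=" * 60]
    for r in calls.to_dict("records"):
        lines.append(
            f"{r['index']} period {r['period']} group {r['group']}: "
            f"d_mu = {r['delta_mu_mean']:+.4f} +/- {r['delta_mu_sd']:.4f} /day, "
            f"d_sigma = {r['delta_sigma_mean']:+.4f} +/- {r['delta_sigma_sd']:.4f} /day "
            f"-> {r['label'].upper()} "
            f"(P[selection] = {r['p_selection']:.2f}, P[drift] = {r['p_drift']:.2f})"
        )
    return "\n".join(lines) + "\n"


__all__ = [
    "classify_assembly", "quadrant_probabilities", "make_assembly_calls",
    "AssemblyCall", "format_report", "LABELS", "QUADRANTS",
]
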