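"""Channel ranking, HFO-area definition and SOZ-overlap scoring.

Channels are ranked by HFO rate; those with a rate strictly above half the
maximum rate form the HFO area, which is scored against the clinically
defined seizure-onset zone (SOZ) channel set as a binary channel classifier:
sensitivity = TP/(TP+FN), specificity = 1 - FP/(FP+TN), with exact
(Clopper-Pearson) binomial confidence intervals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ChannelRates",
    "EvalResult",
    "channel_rates",
    "half_max_area",
    "kittler_area",
    "confusion_and_scores",
    "scores_from_counts",
    "binomial_ci",
    "round_half_away",
]


@dataclass
class ChannelRates:
    """Per-channel HFO counts over an analyzed duration."""

    counts: dict[str, int]
    duration_min: float

    def __post_init__(self) -> None:
        if self.duration_min <= 0:
            raise ValueError("duration must be positive")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("counts must be nonnegative")

    @property
    def rates(self) -> dict[str, float]:
        """Events per minute."""
        return {c: n / self.duration_min for c, n in self.counts.items()}


def channel_rates(
    events_by_channel: Mapping[str, list], duration_s: float,
    accepted_only: bool = True,
) -> ChannelRates:
    """Count (accepted) events per channel and attach the epoch duration."""
    counts = {}
    for label, events in events_by_channel.items():
        if accepted_only:
            counts[label] = sum(1 for e in events if getattr(e, "accepted", True))
        else:
            counts[label] = len(events)
    return ChannelRates(counts, duration_s / 60.0)


def half_max_area(rates: ChannelRates | Mapping[str, float]) -> set[str]:
    """Channels whose HFO rate is strictly above half the maximum rate.

    The maximal channel is always included; with all-zero rates the area is
    empty and a warning is issued.
    """
    if isinstance(rates, ChannelRates):
        rates = rates.rates
    if not rates:
        return set()
    max_rate = max(rates.values())
    if max_rate == 0:
        warnings.warn("all channel rates are zero: empty HFO area", stacklevel=2)
        return set()
    return {c for c, r in rates.items() if r > max_rate / 2.0}


def kittler_area(rates: ChannelRates | Mapping[str, float],
                 n_bins: int = 32) -> set[str]:
    """Alternative channel selection by Kittler-Illingworth minimum-error
    thresholding of the rate histogram (optional; the half-maximum rule is
    the default and the one scored against clinical data)."""
    if isinstance(rates, ChannelRates):
        rates = rates.rates
    vals = np.asarray(list(rates.values()), dtype=float)
    if vals.max() == 0:
        return set()
    hist, edges = np.histogram(vals, bins=n_bins)
    p = hist / hist.sum()
    centers = (edges[:-1] + edges[1:]) / 2
    best_j, best_cost = None, np.inf
    for j in range(1, n_bins):
        w0, w1 = p[:j].sum(), p[j:].sum()
        if w0 <= 0 or w1 <= 0:
            continue
        m0 = (p[:j] * centers[:j]).sum() / w0
        m1 = (p[j:] * centers[j:]).sum() / w1
        v0 = (p[:j] * (centers[:j] - m0) ** 2).sum() / w0
        v1 = (p[j:] * (centers[j:] - m1) ** 2).sum() / w1
        if v0 <= 0 or v1 <= 0:
            continue
        cost = (
            w0 * np.log(np.sqrt(v0) / w0) + w1 * np.log(np.sqrt(v1) / w1)
        )
        if cost < best_cost:
            best_cost, best_j = cost, j
    if best_j is None:
        return half_max_area(rates)
    thr = edges[best_j]
    return {c for c, r in rates.items() if r > thr}


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def binomial_ci(successes: int, trials: int, level: float = 0.95
                ) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval, in percent."""
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not 0 <= successes <= trials:
        raise ValueError("successes must be in [0, trials]")
    from statsmodels.stats.proportion import proportion_confint

    lo, hi = proportion_confint(successes, trials, alpha=1 - level,
                                method="beta")
    return 100.0 * float(lo), 100.0 * float(hi)


def scores_from_counts(tp: int, tn: int, fp: int, fn: int
                       ) -> tuple[float | None, float]:
    """Sensitivity and specificity (integer percent) from confusion counts."""
    sens = (
        float(round_half_away(100.0 * tp / (tp + fn))) if tp + fn > 0 else None
    )
    fpr = fp / (fp + tn) if fp + tn > 0 else 0.0
    spec = float(round_half_away(100.0 * (1.0 - fpr)))
    return sens, spec


@dataclass
class EvalResult:
    """Confusion counts and scores of an HFO area against the SOZ."""

    hfo_area: set[str]
    soz: set[str]
    tp: int
    tn: int
    fp: int
    fn: int
    sens: float | None
    spec: float
    sens_ci: tuple[float, float] | None
    spec_ci: tuple[float, float]

    def summary(self) -> str:
        sens = "n/a" if self.sens is None else f"{self.sens:.0f}%"
        lines = [
            f"HFO area ({len(self.hfo_area)} channels): "
            + ", ".join(sorted(self.hfo_area)),
            f"SOZ ({len(self.soz)} channels): " + ", ".join(sorted(self.soz)),
            f"TP={self.tp} TN={self.tn} FP={self.fp} FN={self.fn}",
            f"sensitivity {sens}  specificity {self.spec:.0f}%",
        ]
        if self.sens_ci is not None:
            lines.append(
                f"95% CI sens [{self.sens_ci[0]:.0f}%, {self.sens_ci[1]:.0f}%]"
                f"  spec [{self.spec_ci[0]:.0f}%, {self.spec_ci[1]:.0f}%]"
            )
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "hfo_area_n": len(self.hfo_area),
                    "hfo_area": ",".join(sorted(self.hfo_area)),
                    "soz": ",".join(sorted(self.soz)),
                    "tp": self.tp,
                    "tn": self.tn,
                    "fp": self.fp,
                    "fn": self.fn,
                    "sens_pct": self.sens,
                    "spec_pct": self.spec,
                }
            ]
        )


def confusion_and_scores(
    area: Iterable[str], soz: Iterable[str], all_channels: Iterable[str]
) -> EvalResult:
    """Score the HFO area against the SOZ over a channel universe.

    TP are area channels inside the SOZ, FP area channels outside it, FN
    SOZ channels missed by the area, TN the rest.  Sensitivity and
    specificity are percentages rounded to the nearest integer (halves away
    from zero).  With an empty SOZ sensitivity is undefined (None); with
    TN+FP = 0 the false-positive rate is taken as 0 so specificity is 100.
    """
    area, soz, universe = set(area), set(soz), set(all_channels)
    if not area <= universe:
        raise ValueError(f"area channels not in channel set: {area - universe}")
    if not soz <= universe:
        raise ValueError(f"SOZ channels not in channel set: {soz - universe}")
    tp = len(area & soz)
    fp = len(area - soz)
    fn = len(soz - area)
    tn = len(universe) - tp - fp - fn
    assert tp + tn + fp + fn == len(universe)

    if tp + fn > 0:
        sens = float(round_half_away(100.0 * tp / (tp + fn)))
        sens_ci = binomial_ci(tp, tp + fn)
    else:
        sens, sens_ci = None, None
    if fp + tn > 0:
        fpr = fp / (fp + tn)
        spec_ci = binomial_ci(tn, fp + tn)
    else:
        fpr = 0.0  # degenerate universe: no negatives to mislabel
        spec_ci = (100.0, 100.0)
    spec = float(round_half_away(100.0 * (1.0 - fpr)))
    return EvalResult(area, soz, tp, tn, fp, fn, sens, spec, sens_ci, spec_ci)
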