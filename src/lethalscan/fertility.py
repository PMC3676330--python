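"""Fertility contrast for matings at risk.

A recessive lethal segregating at frequency f_k reduces the conception rate of
an insemination by the probability that the conceptus is a lethal homozygote.
In a mating at risk — a carrier bull inseminating a daughter of a carrier
sire — that probability is (1/2) * (1/2 + f_k) / 2, so under complete
lethality the expected loss in conception rate is

    loss = -µ * (0.5 + f_k) / 4   ->  -µ/8 as f_k -> 0,

with µ the mean conception rate of the parity class. Averaged over all
daughters of a carrier bull (mated to random bulls) the loss is only
-0.5 * (0.5 + f_k) * f_k * µ, which is why the at-risk contrast, not the
population average, is the detection design.

Heifers and lactating cows are analysed separately: they have different mean
conception rates and give two independent confirmations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

AT_RISK = "at_risk"                  # carrier bull x daughter of carrier sire
CARRIER_BULL = "carrier_bull"        # carrier bull x daughter of noncarrier sire
CARRIER_SIRE = "carrier_sire"        # noncarrier bull x daughter of carrier sire
CONTROL = "control"                  # noncarrier bull x daughter of noncarrier sire

GROUPS = (AT_RISK, CARRIER_BULL, CARRIER_SIRE, CONTROL)


@dataclass
class FertilityResult:
    parity_class: str
    n_at_risk: int
    n_control: int
    loss_pct: float          # rate(at risk) - rate(control), percentage points
    t_statistic: float
    p_value: float
    stars: str

    def row(self) -> dict:
        return {
            "parity_class": self.parity_class,
            "n_at_risk": self.n_at_risk,
            "n_control": self.n_control,
            "loss_pct": round(self.loss_pct, 2),
            "t": round(self.t_statistic, 3) if np.isfinite(self.t_statistic) else "",
            "p": self.p_value,
            "significance": self.stars,
        }


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def classify_matings(
    inseminations: pd.DataFrame,
    bull_status: pd.Series | dict,
    sire_status: pd.Series | dict | None = None,
) -> pd.DataFrame:
    """Attach a mating-group label from the carrier status of the bull and of
    the cow's sire. Records with unknown status on either side are dropped
    (with a logged count), mirroring the known-status restriction of the
    design. Status maps are boolean (True = carrier); missing ids = unknown.
    """
    if sire_status is None:
        sire_status = bull_status
    bull_status = pd.Series(bull_status, dtype="boolean")
    sire_status = pd.Series(sire_status, dtype="boolean")
    bs = bull_status.reindex(inseminations["bull_id"]).to_numpy()
    ss = sire_status.reindex(inseminations["cow_sire_id"]).to_numpy()
    known = pd.notna(bs) & pd.notna(ss)
    dropped = int((~known).sum())
    if dropped:
        logger.info("dropped %d inseminations with unknown bull or cow-sire status", dropped)
    out = inseminations.loc[known].copy()
    bs = bs[known].astype(bool)
    ss = ss[known].astype(bool)
    out["group"] = np.select(
        [bs & ss, bs & ~ss, ~bs & ss], [AT_RISK, CARRIER_BULL, CARRIER_SIRE], CONTROL
    )
    return out


def estimate_loss(
    classified: pd.DataFrame,
    parity_class: str,
    control: str = "noncarrier",
) -> FertilityResult:
    """Raw conception-rate difference (at risk minus control) for one parity
    class, with a Welch two-sample t-test. ``control`` selects the comparison
    group: ``"noncarrier"`` (noncarrier bull x noncarrier sire, default) or
    ``"all"`` (every mating that is not at risk).

    An empty at-risk group reports n=0, loss 0 and no test.
    """
    sub = classified[classified["parity_class"] == parity_class]
    at_risk = sub.loc[sub["group"] == AT_RISK, "outcome"].to_numpy(dtype=float)
    if control == "noncarrier":
        ctrl = sub.loc[sub["group"] == CONTROL, "outcome"].to_numpy(dtype=float)
    elif control == "all":
        ctrl = sub.loc[sub["group"] != AT_RISK, "outcome"].to_numpy(dtype=float)
    else:
        raise ValueError("control must be 'noncarrier' or 'all'")
    if len(at_risk) == 0:
        return FertilityResult(parity_class, 0, len(ctrl), 0.0, float("nan"), 1.0, "")
    if len(ctrl) == 0:
        raise ValueError(f"empty control group for parity class {parity_class!r}")
    loss = 100.0 * (at_risk.mean() - ctrl.mean())
    if len(at_risk) > 1 and len(ctrl) > 1 and (at_risk.std() > 0 or ctrl.std() > 0):
        t, p = stats.ttest_ind(at_risk, ctrl, equal_var=False)
    else:
        t, p = 0.0, 1.0
    return FertilityResult(
        parity_class, len(at_risk), len(ctrl), float(loss), float(t), float(p),
        significance_stars(float(p)),
    )


def fertility_report(
    classified: pd.DataFrame,
    haplotype_name: str = "",
    control: str = "noncarrier",
) -> pd.DataFrame:
    """Heifer and cow rows for one haplotype, Table-2 style."""
    rows = []
    for parity in ("heifer", "cow"):
        res = estimate_loss(classified, parity, control=control)
        row = {"haplotype": haplotype_name}
        row.update(res.row())
        rows.append(row)
    return pd.DataFrame(rows)


def expected_loss_at_risk(f_k: float, mu: float) -> float:
    """Expected conception-rate loss (as a fraction, negative) in matings at
    risk under complete lethality: -µ(0.5 + f_k)/4, i.e. -µ/8 as f_k -> 0."""
    if not 0 <= f_k < 0.5:
        raise ValueError("f_k must be in [0, 0.5)")
    if not 0 <= mu <= 1:
        raise ValueError("mu must be in [0, 1]")
    return -mu * (0.5 + f_k) / 4.0


def expected_loss_daughters(f_k: float, mu: float) -> float:
    """Expected conception-rate loss over all daughters of a carrier bull mated
    to random bulls: -0.5(0.5 + f_k) f_k µ. Small for rare haplotypes, which is
    what motivates contrasting matings at risk instead."""
    if not 0 <= f_k < 0.5:
        raise ValueError("f_k must be in [0, 0.5)")
    if not 0 <= mu <= 1:
        raise ValueError("mu must be in [0, 1]")
    return -0.5 * (0.5 + f_k) * f_k * mu
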