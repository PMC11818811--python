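"""Standard reaction thermodynamics from fitted constants and enthalpies.

Conventions: log K base 10 on the mol dm^-3 scale, T = 298.15 K unless
stated, R = 8.31446 J K^-1 mol^-1; dG and dH in kJ mol^-1, dS in
J K^-1 mol^-1.  dG = -RT ln10 logK; dS = (dH - dG)/T; the entropic term
TdS = dH - dG.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "R_GAS",
    "T_STANDARD",
    "ThermoRecord",
    "gibbs_from_logK",
    "entropy_from",
    "propagate_uncertainty",
    "selectivity_ratio",
    "compare_solvents",
    "records_table",
]

R_GAS = 8.31446  # J K^-1 mol^-1
T_STANDARD = 298.15  # K
_LN10 = math.log(10.0)


def gibbs_from_logK(log_k: float, temperature: float = T_STANDARD) -> float:
    """Standard reaction Gibbs energy, kJ mol^-1: -RT ln10 logK."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return -R_GAS * temperature * _LN10 * log_k / 1000.0


def entropy_from(
    delta_g: float, delta_h: float, temperature: float = T_STANDARD
) -> tuple[float, float]:
    """(dS in J K^-1 mol^-1, TdS in kJ mol^-1) from dG and dH (kJ mol^-1)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    t_ds = delta_h - delta_g
    return 1000.0 * t_ds / temperature, t_ds


def propagate_uncertainty(
    log_k_se: float, delta_h_se: float, temperature: float = T_STANDARD
) -> tuple[float, float]:
    """(se(dG) kJ mol^-1, se(dS) J K^-1 mol^-1) by linear propagation.

    dG depends on logK alone; dS = (dH - dG)/T combines both, treated as
    independent.
    """
    if log_k_se < 0 or delta_h_se < 0:
        raise ValueError("standard errors must be non-negative")
    se_g = R_GAS * temperature * _LN10 * log_k_se / 1000.0
    se_s = 1000.0 * math.sqrt(delta_h_se**2 + se_g**2) / temperature
    return se_g, se_s


def selectivity_ratio(log_k_a: float, log_k_b: float, round_to_power_of_ten: bool = False) -> float:
    """K_a / K_b, optionally rounded to the nearest power of ten."""
    if round_to_power_of_ten:
        return 10.0 ** round(log_k_a - log_k_b)
    return 10.0 ** (log_k_a - log_k_b)


@dataclass
class ThermoRecord:
    """One cation/solvent row of a thermodynamic results table.

    Missing quantities are None.  Construction back-fills dG from logK and
    dS (+ TdS) from dH and dG when not supplied, which keeps the internal
    identities exact; printed-precision tables should be built through
    :func:`records_table`.
    """

    cation: str
    solvent: str
    log_k: float
    log_k_se: float = 0.0
    delta_h: float | None = None  # kJ mol^-1
    delta_h_se: float | None = None
    temperature: float = T_STANDARD
    methods: tuple[str, ...] = ("spectrophotometry",)
    delta_g: float = field(init=False)
    delta_g_se: float = field(init=False)
    delta_s: float | None = field(init=False, default=None)
    delta_s_se: float | None = field(init=False, default=None)
    t_delta_s: float | None = field(init=False, default=None)

    def __post_init__(self) -> None:
        if not self.methods:
            raise ValueError("at least one method tag required")
        self.delta_g = gibbs_from_logK(self.log_k, self.temperature)
        self.delta_g_se, se_s = propagate_uncertainty(
            self.log_k_se, self.delta_h_se or 0.0, self.temperature
        )
        if self.delta_h is not None:
            self.delta_s, self.t_delta_s = entropy_from(self.delta_g, self.delta_h, self.temperature)
            self.delta_s_se = se_s


def records_table(records: list[ThermoRecord]) -> pd.DataFrame:
    """Report table mimicking the experimental-tables rounding: dG/dH to
    one decimal, dS to integer, logK to two decimals."""
    rows = []
    for r in records:
        rows.append(
            {
                "solvent": r.solvent,
                "cation": r.cation,
                "logK": round(r.log_k, 2),
                "dG/kJ mol-1": round(r.delta_g, 1),
                "dH/kJ mol-1": None if r.delta_h is None else round(r.delta_h, 1),
                "dS/J K-1 mol-1": None if r.delta_s is None else round(r.delta_s),
                "TdS/kJ mol-1": None if r.t_delta_s is None else round(r.t_delta_s, 1),
                "methods": "+".join(r.methods),
            }
        )
    return pd.DataFrame(rows)


RANKING_EQUIV_MARGIN = 0.2  # log units; ~1.6-fold in K


def _ranking(records: list[ThermoRecord]) -> str:
    """Stability ordering string.

    '≈' joins constants that differ by less than twice the combined
    standard error or by less than a practical-equivalence margin of 0.2
    log units (experimental repeatability across methods is of that
    order, and a 1.6-fold difference in K is not a meaningful
    selectivity).
    """
    rs = sorted(records, key=lambda r: -r.log_k)
    parts = [rs[0].cation]
    for prev, cur in zip(rs, rs[1:]):
        comb = max(2.0 * math.hypot(prev.log_k_se, cur.log_k_se), RANKING_EQUIV_MARGIN)
        sep = " ≈ " if abs(prev.log_k - cur.log_k) < comb else " > "
        parts.append(sep + cur.cation)
    return "".join(parts)


def compare_solvents(records: list[ThermoRecord]) -> dict:
    """Cross-solvent comparison for cations measured in several solvents.

    Returns ``{"pairwise": DataFrame, "rankings": {solvent: str}}`` where
    the pairwise table holds d(logK), ddG, ddH and TddS (first solvent
    minus second) per cation and solvent pair.
    """
    by_solvent: dict[str, dict[str, ThermoRecord]] = {}
    for r in records:
        by_solvent.setdefault(r.solvent, {})[r.cation] = r
    solvents = sorted(by_solvent)
    rows = []
    for i, sa in enumerate(solvents):
        for sb in solvents[i + 1 :]:
            shared = sorted(set(by_solvent[sa]) & set(by_solvent[sb]))
            for cat in shared:
                a, b = by_solvent[sa][cat], by_solvent[sb][cat]
                row = {
                    "cation": cat,
                    "solvent_a": sa,
                    "solvent_b": sb,
                    "dlogK": a.log_k - b.log_k,
                    "ddG/kJ mol-1": a.delta_g - b.delta_g,
                }
                if a.delta_h is not None and b.delta_h is not None:
                    row["ddH/kJ mol-1"] = a.delta_h - b.delta_h
                    row["TddS/kJ mol-1"] = a.t_delta_s - b.t_delta_s
                rows.append(row)
    if not rows:
        raise ValueError("no cation measured in more than one solvent")
    rankings = {s: _ranking(list(d.values())) for s, d in by_solvent.items() if len(d) > 1}
    return {"pairwise": pd.DataFrame(rows), "rankings": rankings}
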