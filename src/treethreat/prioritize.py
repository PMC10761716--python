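"""Prioritization of species for Red List re-evaluation.

Exposure thresholds are data-driven: with no literature-defined cut-offs,
the 95th percentile of each threat's rate distribution (zeros from
non-significant trends included) marks "highly exposed". Unidirectional
threats flag the upper tail only; bidirectional threats (burned area,
climate) flag both tails, since both increases and decreases are ecological
signals. Minimal-area species are priority candidates by default — their
occupied area alone meets the Critically-Endangered occupancy bound or the
data are too sparse to trust a data-driven rate.

IUCN Red List categories are lumped into coarse groups for the congruence
analysis: Threatened (EX, EW, RE, CR, EN), Vulnerable (VU), Not Threatened
(LC, NT and the legacy LR/* codes), Data Deficient and Not Evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rrc import BIDIRECTIONAL_THREATS

DEFAULT_QUANTILE = 0.95
MIN_SPECIES_FOR_THRESHOLD = 20

STATUS_GROUPS = {
    "EX": "Threatened", "EW": "Threatened", "RE": "Threatened",
    "CR": "Threatened", "EN": "Threatened",
    "VU": "Vulnerable",
    "LC": "Not Threatened", "NT": "Not Threatened", "LR/lc": "Not Threatened",
    "LR/cd": "Not Threatened", "LR/nt": "Not Threatened",
    "DD": "Data Deficient",
    "NE": "Not Evaluated",
}

GROUP_ORDER = ["Threatened", "Vulnerable", "Not Threatened", "Data Deficient", "Not Evaluated"]


def status_group(code) -> str:
    """Map an IUCN category code to its conservation status group.

    Missing codes (None/NaN/empty) mean the species was never assessed and
    map to Not Evaluated; an unrecognized non-missing code is an error.
    """
    if code is None or (isinstance(code, float) and np.isnan(code)) or code == "":
        return "Not Evaluated"
    try:
        return STATUS_GROUPS[code]
    except KeyError:
        raise ValueError(f"unrecognized IUCN category code {code!r}") from None


@dataclass(frozen=True)
class ThresholdSet:
    """Per-threat exposure thresholds at one quantile level."""

    quantile: float
    upper: dict[str, float]
    lower: dict[str, float]  # bidirectional threats only

    def as_dict(self) -> dict:
        return {
            "quantile": self.quantile,
            "upper": dict(sorted(self.upper.items())),
            "lower": dict(sorted(self.lower.items())),
        }


def compute_thresholds(
    table: pd.DataFrame,
    q: float = DEFAULT_QUANTILE,
    bidirectional: frozenset[str] | set[str] = BIDIRECTIONAL_THREATS,
    min_n: int = MIN_SPECIES_FOR_THRESHOLD,
) -> ThresholdSet:
    """Empirical per-threat quantile thresholds over assessable species.

    Computed over non-removed, non-imputed rates, zeros included; type-7
    (linear-interpolation) quantiles. Bidirectional threats get both the
    q and 1-q tails.
    """
    base = table[~table["outlier_removed"] & ~table["imputed"] & ~table["minimal_area"]]
    upper: dict[str, float] = {}
    lower: dict[str, float] = {}
    for threat, g in base.groupby("threat"):
        rates = g["rate"].to_numpy(dtype=float)
        if rates.size < min_n:
            raise ValueError(
                f"threat {threat!r} has only {rates.size} species; need >= {min_n}"
            )
        upper[threat] = float(np.quantile(rates, q))
        if threat in bidirectional:
            lower[threat] = float(np.quantile(rates, 1.0 - q))
    return ThresholdSet(q, upper, lower)


def flag_candidates(
    table: pd.DataFrame,
    thresholds: ThresholdSet,
    minimal_flags: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-species candidate flags against the exposure thresholds.

    A species is flagged for a threat when its rate strictly exceeds the
    upper threshold (or, for bidirectional threats, falls strictly below
    the lower one). Imputed rates of minimal-area species are compared the
    same way, but a minimal-area species is a priority candidate regardless
    (reason ``minimal_area``). Output: one row per species with per-threat
    boolean columns, ``n_threats_flagged``, ``priority`` and ``reason``.
    """
    base = table[~table["outlier_removed"]]
    threats = sorted(thresholds.upper)
    flags = {}
    for threat in threats:
        g = base[base["threat"] == threat]
        rate = g.set_index("species_id")["rate"]
        hi = rate > thresholds.upper[threat]
        if threat in thresholds.lower:
            hi = hi | (rate < thresholds.lower[threat])
        flags[threat] = hi
    out = pd.DataFrame(flags).fillna(False).astype(bool)
    out.index.name = "species_id"
    minimal_ids: set[str] = set()
    if minimal_flags is not None:
        minimal_ids = set(minimal_flags.loc[minimal_flags["flagged"], "species_id"])
        missing = minimal_ids - set(out.index)
        if missing:
            pad = pd.DataFrame(False, index=sorted(missing), columns=out.columns)
            pad.index.name = "species_id"
            out = pd.concat([out, pad])
    out["n_threats_flagged"] = out[threats].sum(axis=1).astype(int)
    out["minimal_area"] = out.index.isin(minimal_ids)
    out["priority"] = (out["n_threats_flagged"] > 0) | out["minimal_area"]
    out["reason"] = np.select(
        [out["minimal_area"], out["n_threats_flagged"] > 0],
        ["minimal_area", "high_exposure"],
        default="",
    )
    return out.sort_index().reset_index()


def congruence_summary(candidates: pd.DataFrame, statuses: pd.DataFrame) -> pd.DataFrame:
    """Cross-tab of priority candidacy against conservation status groups.

    Returns one row per status group with the group's size, its number of
    candidates, the share of candidates belonging to the group, and the
    share of the group that is candidate. Species without a status row are
    Not Evaluated.
    """
    merged = candidates.merge(statuses, on="species_id", how="left")
    merged["group"] = merged["iucn_code"].map(status_group)
    n_cand = int(merged["priority"].sum())
    rows = []
    for group in GROUP_ORDER:
        g = merged[merged["group"] == group]
        k = int(g["priority"].sum())
        rows.append({
            "group": group,
            "n_species": int(len(g)),
            "n_candidates": k,
            "pct_of_candidates": 100.0 * k / n_cand if n_cand else 0.0,
            "pct_of_group_candidate": 100.0 * k / len(g) if len(g) else 0.0,
        })
    return pd.DataFrame(rows)
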