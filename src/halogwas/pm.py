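"""Phenotype-Microarray carbon-source utilization under salt stress.

Each PM1/PM2 well holds one carbon source; the area under its respiration
curve (AOU) measures utilization. A well is 'active' when its area reaches
the activity threshold (default 13,000 AOU, set from the maximum
negative-control area; raw areas are thresholded, no control subtraction).
From per-strain active sets the module computes utilization counts under
no-salt and salt conditions, retention percentages, and the carbon sources
that tolerant strains keep using under salt while a sensitive strain defines
the common baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import pandas as pd

ACTIVITY_THRESHOLD = 13000.0


@dataclass
class UtilizationSummary:
    strain_id: str
    salt_condition: str
    n_active: int
    active_set: frozenset


def call_active(area: float, threshold: float = ACTIVITY_THRESHOLD) -> bool:
    """Active iff area >= threshold; areas below reflect no metabolism."""
    if area < 0:
        raise ValueError("area must be non-negative")
    return area >= threshold


def summarize_utilization(areas: pd.DataFrame,
                          threshold: float = ACTIVITY_THRESHOLD) -> list:
    """Active-substrate sets per strain x salt condition.

    ``areas`` is long-format with columns (strain, substrate, condition,
    area); substrate labels are matched case-insensitively. PM runs carry no
    technical replicates; a duplicate (strain, substrate, condition) row is
    an error.
    """
    required = {"strain", "substrate", "condition", "area"}
    if not required.issubset(areas.columns):
        raise ValueError(f"areas table needs columns {sorted(required)}")
    df = areas.copy()
    df["substrate"] = df["substrate"].str.strip().str.lower()
    keys = df[["strain", "substrate", "condition"]]
    if keys.duplicated().any():
        dup = keys[keys.duplicated()].iloc[0]
        raise ValueError(f"duplicate PM well for {tuple(dup)}")
    out = []
    for (strain, cond), grp in df.groupby(["strain", "condition"],
                                          sort=True):
        active = frozenset(grp.loc[grp["area"] >= threshold, "substrate"])
        out.append(UtilizationSummary(strain_id=strain,
                                      salt_condition=str(cond),
                                      n_active=len(active),
                                      active_set=active))
    return out


def retention_percent(n_control: int, n_salt: int) -> int:
    """Percent of normally catabolised sources still used under salt.

    Reported as a whole percent, rounded up (a strain using any fraction of
    the next percent is credited with it; exact multiples are unchanged).
    """
    if n_control <= 0:
        raise ValueError("n_control must be positive")
    return int(math.ceil(100.0 * n_salt / n_control - 1e-9))


def common_retained(summaries: list, tolerant: list, sensitive: list,
                    areas: pd.DataFrame | None = None,
                    ratio_cutoff: float = 0.5,
                    control_condition: str = "0",
                    salt_condition: str = "300"):
    """Common control-active sources and the subset tolerant strains retain.

    ``common_set`` is the intersection of every listed strain's active set at
    the control condition. A common source is 'retained' when every tolerant
    strain is active on it under salt AND (when ``areas`` is given) keeps an
    area ratio salt/control >= ``ratio_cutoff``. Returns
    (common_set, retained_set).
    """
    if not tolerant or not sensitive:
        raise ValueError("need at least one tolerant and one sensitive strain")
    by_key = {(s.strain_id, s.salt_condition): s for s in summaries}

    def active_set(strain, cond):
        key = (strain, cond)
        return by_key[key].active_set if key in by_key else frozenset()

    strains = list(tolerant) + [s for s in sensitive if s not in tolerant]
    common = None
    for strain in strains:
        s = active_set(strain, control_condition)
        common = s if common is None else (common & s)
    common = common or frozenset()

    ratio_ok = None
    if areas is not None:
        df = areas.copy()
        df["substrate"] = df["substrate"].str.strip().str.lower()
        df["condition"] = df["condition"].astype(str)
        piv = df.pivot_table(index=["strain", "substrate"],
                             columns="condition", values="area")

        def ratio_ok(strain, substrate):
            try:
                row = piv.loc[(strain, substrate)]
            except KeyError:
                return False
            ctrl = row.get(control_condition)
            salt = row.get(salt_condition)
            if ctrl is None or salt is None or pd.isna(ctrl) or ctrl <= 0:
                return False
            return salt / ctrl >= ratio_cutoff

    retained = set()
    for substrate in common:
        ok = all(substrate in active_set(t, salt_condition)
                 for t in tolerant)
        if ok and ratio_ok is not None:
            ok = all(ratio_ok(t, substrate) for t in tolerant)
        if ok:
            retained.add(substrate)
    return frozenset(common), frozenset(retained)


def load_reported_utilization() -> pd.DataFrame:
    """Published per-strain carbon-source utilization counts (0 vs 300 mM
    NaCl, out of 190 PM1+PM2 sources) shipped as package data."""
    with resources.files("halogwas").joinpath(
            "data/pm_utilization_counts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_reported_retained_sources() -> list:
    """Published list of carbon sources on which salt-tolerant strains keep
    high metabolic activity under 300 mM NaCl (one substrate per line)."""
    with resources.files("halogwas").joinpath(
            "data/retained_carbon_sources.txt").open() as fh:
        return [line.strip() for line in fh
                if line.strip() and not line.startswith("#")]
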