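"""SF-12 scoring, SF-6D health-state classification, and utility valuation.

The 12-item short-form health survey is scored into norm-based physical
(PCS) and mental (MCS) component summaries with published regression
weights, classified into the six-dimensional SF-6D health state, and valued
by an additive-decrement preference tariff. Coefficients live in versioned
CSV files (checksummed at load time), never in code, so alternative weight
sets or tariffs can be swapped in.

Item coding (version 1 instrument, natural questionnaire order):

==== ==========================================  ======  ==========
code  content                                    levels  best level
==== ==========================================  ======  ==========
gh1   general health (excellent..poor)              5        1
pf02  moderate activities limited (a lot..not)      3        3
pf04  climbing stairs limited (a lot..not)          3        3
rp2   accomplished less, physical (yes/no)          2        2
rp3   limited in kind of work (yes/no)              2        2
re2   accomplished less, emotional (yes/no)         2        2
re3   worked less carefully (yes/no)                2        2
bp2   pain interfered with work (not..extremely)    5        1
mh3   felt calm and peaceful (all..none of time)    6        1
vt2   had a lot of energy (all..none of time)       6        1
mh4   felt downhearted (all..none of time)          6        6
sf2   social activities interfered (all..none)      5        5
==== ==========================================  ======  ==========

A visit with any missing item yields no scores (complete-case per visit);
the caller handles it through last-observation-carried-forward imputation.
"""

from __future__ import annotations

import hashlib
import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

#: item code -> (number of levels, driving latent domain, best response level)
SF12_ITEMS: dict[str, tuple[int, str, int]] = {
    "gh1": (5, "phys", 1),
    "pf02": (3, "phys", 3),
    "pf04": (3, "phys", 3),
    "rp2": (2, "phys", 2),
    "rp3": (2, "phys", 2),
    "re2": (2, "ment", 2),
    "re3": (2, "ment", 2),
    "bp2": (5, "phys", 1),
    "mh3": (6, "ment", 1),
    "vt2": (6, "ment", 1),
    "mh4": (6, "ment", 6),
    "sf2": (5, "ment", 5),
}
ITEM_COLUMNS = tuple(SF12_ITEMS)

SF6D_DIMENSIONS = ("pf", "rl", "sf", "pain", "mh", "vit")
SF6D_MAX_LEVEL = {"pf": 3, "rl": 4, "sf": 5, "pain": 5, "mh": 5, "vit": 5}

#: Items required to classify the SF-6D state from SF-12 responses.
SF6D_REQUIRED_ITEMS = ("pf02", "rp2", "re2", "sf2", "bp2", "mh4", "vt2")

# item-response -> dimension-level maps (6-category items collapse
# "a good bit of the time" with "some of the time" into level 3)
_PF_MAP = {3: 1, 2: 2, 1: 3}
_SF_MAP = {5: 1, 4: 2, 3: 3, 2: 4, 1: 5}
_MH_MAP = {6: 1, 5: 2, 4: 3, 3: 3, 2: 4, 1: 5}
_VIT_MAP = {1: 1, 2: 2, 3: 3, 4: 3, 5: 4, 6: 5}


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _resource(name: str):
    return importlib.resources.files("psycea.data") / name


@dataclass(frozen=True)
class Sf12Weights:
    """Norm-based PCS/MCS regression weights keyed by (item, response)."""

    pcs: dict[tuple[str, int], float]
    mcs: dict[tuple[str, int], float]
    pcs_constant: float
    mcs_constant: float
    version: str
    checksum: str


def load_sf12_weights(path: str | Path | None = None) -> Sf12Weights:
    """Load PCS/MCS scoring weights; default is the shipped US 1998 set."""
    if path is None:
        ref = _resource("sf12_weights_us1998.csv")
        with importlib.resources.as_file(ref) as p:
            return load_sf12_weights(p)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"SF-12 weight file not found: {path}")
    df = pd.read_csv(path, comment="#")
    expected = {"component", "item", "response", "weight"}
    if set(df.columns) != expected:
        raise ValueError(f"malformed SF-12 weight file {path}: columns {list(df.columns)}")
    weights: dict[str, dict[tuple[str, int], float]] = {"pcs": {}, "mcs": {}}
    constants = {}
    for rec in df.itertuples(index=False):
        if rec.item == "_constant":
            constants[rec.component] = float(rec.weight)
        else:
            weights[rec.component][(rec.item, int(rec.response))] = float(rec.weight)
    return Sf12Weights(
        pcs=weights["pcs"],
        mcs=weights["mcs"],
        pcs_constant=constants["pcs"],
        mcs_constant=constants["mcs"],
        version=path.stem,
        checksum=_checksum(path),
    )


@dataclass(frozen=True)
class Sf6dTariff:
    """Additive-decrement SF-6D tariff: utility = 1 − Σ decrements − MOST penalty."""

    decrements: dict[tuple[str, int], float]
    most_penalty: float
    version: str
    checksum: str

    @property
    def floor(self) -> float:
        """Utility of the worst classifiable state."""
        worst = sum(
            self.decrements[(d, SF6D_MAX_LEVEL[d])] for d in SF6D_DIMENSIONS
        )
        return 1.0 - worst - self.most_penalty


def load_sf6d_tariff(path: str | Path | None = None) -> Sf6dTariff:
    """Load an SF-6D tariff; default is the shipped synthetic stand-in set."""
    if path is None:
        ref = _resource("sf6d_sf12_tariff_synthetic.csv")
        with importlib.resources.as_file(ref) as p:
            return load_sf6d_tariff(p)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"SF-6D tariff file not found: {path}")
    df = pd.read_csv(path, comment="#")
    if set(df.columns) != {"dimension", "level", "decrement"}:
        raise ValueError(f"malformed tariff file {path}: columns {list(df.columns)}")
    decrements: dict[tuple[str, int], float] = {}
    most = 0.0
    for rec in df.itertuples(index=False):
        if rec.dimension == "_most":
            most = float(rec.decrement)
        else:
            decrements[(rec.dimension, int(rec.level))] = float(rec.decrement)
    for dim in SF6D_DIMENSIONS:
        for level in range(2, SF6D_MAX_LEVEL[dim] + 1):
            if (dim, level) not in decrements:
                raise ValueError(f"tariff file {path} missing decrement for {dim} level {level}")
        decrements.setdefault((dim, 1), 0.0)
    return Sf6dTariff(
        decrements=decrements,
        most_penalty=most,
        version=path.stem,
        checksum=_checksum(path),
    )


def _validate_items(responses: pd.DataFrame) -> pd.DataFrame:
    missing_cols = [c for c in ITEM_COLUMNS if c not in responses.columns]
    if missing_cols:
        raise ValueError(f"response table missing item columns: {missing_cols}")
    for item, (levels, _, _) in SF12_ITEMS.items():
        col = responses[item]
        bad = col.notna() & (~col.isin(range(1, levels + 1)))
        if bad.any():
            raise ValueError(
                f"item {item!r} has out-of-range responses: {sorted(col[bad].unique())}"
            )
    return responses


def score_sf12(responses: pd.DataFrame, weights: Sf12Weights | None = None) -> pd.DataFrame:
    """Score responses into PCS/MCS T-scores (NaN for incomplete visits).

    ``responses`` has one row per client-visit with columns ``client_id``,
    ``visit`` and the twelve item columns. Scores are the regression
    constant plus the indicator weight of each item's observed response.
    """
    if weights is None:
        weights = load_sf12_weights()
    _validate_items(responses)
    complete = responses[list(ITEM_COLUMNS)].notna().all(axis=1)
    pcs = pd.Series(np.nan, index=responses.index, dtype=float)
    mcs = pd.Series(np.nan, index=responses.index, dtype=float)
    pcs[complete] = weights.pcs_constant
    mcs[complete] = weights.mcs_constant
    for item in ITEM_COLUMNS:
        resp = responses.loc[complete, item].astype(int)
        pcs[complete] += resp.map(lambda r, i=item: weights.pcs.get((i, r), 0.0))
        mcs[complete] += resp.map(lambda r, i=item: weights.mcs.get((i, r), 0.0))
    return pd.DataFrame(
        {"client_id": responses["client_id"], "visit": responses["visit"], "pcs": pcs, "mcs": mcs}
    )


def sf12_to_sf6d(responses: pd.DataFrame) -> pd.DataFrame:
    """Classify responses into SF-6D dimension levels (NaN where items are missing.)

    Dimensions: physical functioning (pf, from pf02), role limitation (rl,
    from rp2 × re2: 1 none, 2 physical only, 3 emotional only, 4 both),
    social functioning (sf, from sf2), pain (from bp2), mental health (mh,
    from mh4) and vitality (vit, from vt2).
    """
    _validate_items(responses)
    complete = responses[list(SF6D_REQUIRED_ITEMS)].notna().all(axis=1)
    out = pd.DataFrame(
        {"client_id": responses["client_id"], "visit": responses["visit"]},
        index=responses.index,
    )
    for dim in SF6D_DIMENSIONS:
        out[dim] = np.nan
    sub = responses[complete]
    out.loc[complete, "pf"] = sub["pf02"].map(_PF_MAP)
    out.loc[complete, "rl"] = (
        1 + (sub["rp2"] == 1).astype(int) + 2 * (sub["re2"] == 1).astype(int)
    )
    out.loc[complete, "sf"] = sub["sf2"].map(_SF_MAP)
    out.loc[complete, "pain"] = sub["bp2"].astype(int)
    out.loc[complete, "mh"] = sub["mh4"].map(_MH_MAP)
    out.loc[complete, "vit"] = sub["vt2"].map(_VIT_MAP)
    return out


def sf6d_utility(states: pd.DataFrame, tariff: Sf6dTariff | None = None) -> pd.Series:
    """Value SF-6D states: utility = 1 − Σ level decrements − MOST penalty.

    The MOST penalty applies once when any dimension is at its most severe
    level. Rows with any missing dimension yield NaN.
    """
    if tariff is None:
        tariff = load_sf6d_tariff()
    complete = states[list(SF6D_DIMENSIONS)].notna().all(axis=1)
    utility = pd.Series(np.nan, index=states.index, dtype=float)
    sub = states[complete]
    total = pd.Series(0.0, index=sub.index)
    any_most = pd.Series(False, index=sub.index)
    for dim in SF6D_DIMENSIONS:
        levels = sub[dim].astype(int)
        bad = ~levels.isin(range(1, SF6D_MAX_LEVEL[dim] + 1))
        if bad.any():
            raise ValueError(f"dimension {dim!r} has invalid levels: {sorted(levels[bad].unique())}")
        total += levels.map(lambda lv, d=dim: tariff.decrements[(d, lv)])
        any_most |= levels == SF6D_MAX_LEVEL[dim]
    utility[complete] = 1.0 - total - any_most * tariff.most_penalty
    return utility


def utilities_from_sf12(
    responses: pd.DataFrame, tariff: Sf6dTariff | None = None
) -> pd.DataFrame:
    """SF-12 responses → per-visit utilities (columns client_id, visit, utility)."""
    states = sf12_to_sf6d(responses)
    return pd.DataFrame(
        {
            "client_id": states["client_id"],
            "visit": states["visit"],
            "utility": sf6d_utility(states, tariff),
        }
    )


def impute_qol_locf(utilities: pd.DataFrame, n_visits: int = 4) -> pd.DataFrame:
    """Complete utility trajectories by last observation carried forward.

    Input: long table (client_id, visit, utility) with observed visits only
    (or NaN utilities). Output: one row per client per visit 0..n_visits−1
    with an ``imputed`` flag. A missing baseline is an error — such clients
    must be excluded upstream.
    """
    wide = (
        utilities.pivot_table(index="client_id", columns="visit", values="utility")
        .reindex(columns=range(n_visits))
        .sort_index()
    )
    if wide[0].isna().any():
        offenders = wide.index[wide[0].isna()].tolist()
        raise ValueError(f"missing baseline utility for clients: {offenders}")
    observed = wide.notna()
    filled = wide.ffill(axis=1)
    long = filled.stack().rename("utility").reset_index()
    flags = (~observed).stack().rename("imputed").reset_index()
    out = long.merge(flags, on=["client_id", "visit"])
    return out.sort_values(["client_id", "visit"]).reset_index(drop=True)


def qol_summary(
    scores: pd.DataFrame, trajectories: pd.DataFrame, n_visits: int = 4
) -> pd.DataFrame:
    """Per-visit mean (95% CI) of PCS, MCS and LOCF-completed utility."""
    rows = []
    for visit in range(n_visits):
        rec: dict[str, float] = {"visit": visit}
        sc = scores[scores["visit"] == visit]
        for col in ("pcs", "mcs"):
            vals = sc[col].dropna()
            rec[f"{col}_mean"] = vals.mean()
            se = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan
            rec[f"{col}_ci_low"] = rec[f"{col}_mean"] - 1.959963984540054 * se
            rec[f"{col}_ci_high"] = rec[f"{col}_mean"] + 1.959963984540054 * se
        ut = trajectories.loc[trajectories["visit"] == visit, "utility"]
        rec["utility_mean"] = ut.mean()
        se = ut.std(ddof=1) / np.sqrt(len(ut)) if len(ut) > 1 else np.nan
        rec["utility_ci_low"] = rec["utility_mean"] - 1.959963984540054 * se
        rec["utility_ci_high"] = rec["utility_mean"] + 1.959963984540054 * se
        rows.append(rec)
    return pd.DataFrame(rows)
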