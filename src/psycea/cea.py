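"""Cost-effectiveness analysis: CE plane, bootstrap, acceptability curve.

Per-client paired differences (Δcost = post − pre annual cost, ΔQALY =
post − pre QALY) are combined into the cohort-level cost-effectiveness
result. Uncertainty is assessed by a nonparametric client-level bootstrap
(n-out-of-n resampling with replacement, cost–QALY pairs kept intact); the
cost-effectiveness acceptability curve (CEAC) reports, for each willingness
to pay λ, the fraction of bootstrap replicates with positive net monetary
benefit λ·ΔQALY − ΔCost.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


class ClientMismatchError(ValueError):
    """Cost and QALY inputs do not cover the same clients."""


@dataclass(frozen=True)
class QuadrantResult:
    """CE-plane classification of a (Δcost, ΔQALY) point."""

    label: str  # dominant | northeast | dominated | southwest | no_effect
    icer: float | None  # EUR per QALY where defined

    @property
    def is_dominant(self) -> bool:
        return self.label == "dominant"


@dataclass(frozen=True)
class BootstrapResult:
    """B bootstrap replicates of the cohort mean (Δcost, ΔQALY)."""

    draws: pd.DataFrame  # columns delta_cost, delta_qaly; one row per replicate
    B: int
    seed: int

    def __post_init__(self) -> None:
        if len(self.draws) != self.B:
            raise ValueError(f"expected {self.B} draws, got {len(self.draws)}")


def client_deltas(
    cost_pre: pd.Series, cost_post: pd.Series, qaly_pairs: pd.DataFrame
) -> pd.DataFrame:
    """Per-client paired (Δcost, ΔQALY); inputs must cover the same clients.

    ``cost_pre``/``cost_post`` are per-client annual EUR indexed by
    client_id; ``qaly_pairs`` is the output of :func:`psycea.qaly.qaly_deltas`.
    """
    qaly = qaly_pairs.set_index("client_id")
    sets = {
        "cost_pre": set(cost_pre.index),
        "cost_post": set(cost_post.index),
        "qaly": set(qaly.index),
    }
    union = set.union(*sets.values())
    inter = set.intersection(*sets.values())
    if union != inter:
        offenders = sorted(union - inter)
        raise ClientMismatchError(f"client sets differ across inputs; offenders: {offenders}")
    ids = sorted(inter)
    return pd.DataFrame(
        {
            "client_id": ids,
            "delta_cost": (cost_post.reindex(ids) - cost_pre.reindex(ids)).to_numpy(),
            "delta_qaly": qaly["delta"].reindex(ids).to_numpy(),
        }
    )


def classify_quadrant(mean_delta_cost: float, mean_delta_qaly: float) -> QuadrantResult:
    """Locate the mean effect on the CE plane and form the ICER where defined.

    More effect at lower cost is *dominant* (no ICER); less effect at higher
    cost is *dominated*; the two remaining quadrants report ΔCost/ΔQALY.
    Zero ΔQALY leaves the ICER undefined.
    """
    dc, dq = float(mean_delta_cost), float(mean_delta_qaly)
    if not (np.isfinite(dc) and np.isfinite(dq)):
        raise ValueError("deltas must be finite")
    if dq == 0.0:
        return QuadrantResult("no_effect", None)
    if dq > 0 and dc < 0:
        return QuadrantResult("dominant", None)
    if dq > 0 and dc >= 0:
        return QuadrantResult("northeast", dc / dq)
    if dq < 0 and dc > 0:
        return QuadrantResult("dominated", None)
    return QuadrantResult("southwest", dc / dq)


def bootstrap_ce(deltas: pd.DataFrame, B: int = 1000, seed: int = 0) -> BootstrapResult:
    """Client-level bootstrap of the mean (Δcost, ΔQALY).

    Each replicate resamples the n clients with replacement (n out of n),
    keeping every client's cost–QALY pair intact, and records the resampled
    means. Reproducible under a fixed seed.
    """
    if B < 1:
        raise ValueError(f"B must be >= 1, got {B}")
    n = len(deltas)
    if n < 1:
        raise ValueError("need at least one client to bootstrap")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    dc = deltas["delta_cost"].to_numpy()[idx].mean(axis=1)
    dq = deltas["delta_qaly"].to_numpy()[idx].mean(axis=1)
    return BootstrapResult(
        draws=pd.DataFrame({"delta_cost": dc, "delta_qaly": dq}), B=B, seed=seed
    )


def ceac(bootstrap: BootstrapResult, lambda_grid) -> pd.DataFrame:
    """Acceptability curve: P(net monetary benefit > 0) per willingness to pay.

    NMB = λ·ΔQALY − ΔCost per replicate; ties (NMB exactly 0) count as not
    cost-effective.
    """
    lam = np.asarray(lambda_grid, dtype=float)
    if lam.size == 0:
        raise ValueError("lambda grid must not be empty")
    if np.any(lam < 0):
        raise ValueError("willingness-to-pay values must be >= 0")
    dc = bootstrap.draws["delta_cost"].to_numpy()
    dq = bootstrap.draws["delta_qaly"].to_numpy()
    nmb = lam[:, None] * dq[None, :] - dc[None, :]
    prob = (nmb > 0).mean(axis=1)
    return pd.DataFrame({"lambda_eur_per_qaly": lam, "probability": prob})


def default_lambda_grid(max_lambda: float = 100_000.0, step: float = 1_000.0) -> np.ndarray:
    """Willingness-to-pay grid 0..max in EUR/QALY steps (covers 50,000 EUR)."""
    return np.arange(0.0, max_lambda + step / 2, step)


def ce_outputs(
    bootstrap: BootstrapResult,
    ceac_points: pd.DataFrame,
    outdir: str | Path,
    mean_delta_cost: float | None = None,
    mean_delta_qaly: float | None = None,
    plots: bool = False,
) -> dict[str, Path]:
    """Write CE-plane draws, CEAC points and a JSON summary to ``outdir``.

    Means default to the bootstrap-draw means if the observed cohort means
    are not supplied. With ``plots=True`` a CE-plane scatter and CEAC line
    plot are rendered as PNGs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    plane = bootstrap.draws.copy()
    plane.insert(0, "draw_index", np.arange(len(plane)))
    plane = plane.rename(columns={"delta_cost": "delta_cost_eur"})
    plane_path = outdir / "ce_plane.csv"
    plane.to_csv(plane_path, index=False)
    ceac_path = outdir / "ceac.csv"
    ceac_points.to_csv(ceac_path, index=False)

    dc = mean_delta_cost if mean_delta_cost is not None else float(plane["delta_cost_eur"].mean())
    dq = mean_delta_qaly if mean_delta_qaly is not None else float(plane["delta_qaly"].mean())
    quad = classify_quadrant(dc, dq)
    summary = {
        "mean_delta_cost_eur": dc,
        "mean_delta_qaly": dq,
        "quadrant": quad.label,
        "icer_eur_per_qaly": quad.icer,
        "B": bootstrap.B,
        "seed": bootstrap.seed,
    }
    summary_path = outdir / "ce_summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")

    paths = {"ce_plane": plane_path, "ceac": ceac_path, "ce_summary": summary_path}
    if plots:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(plane["delta_qaly"], plane["delta_cost_eur"], s=4, alpha=0.4)
        ax.axhline(0, color="k", lw=0.8)
        ax.axvline(0, color="k", lw=0.8)
        ax.set_xlabel("ΔQALY")
        ax.set_ylabel("ΔCost (EUR)")
        ax.set_title("Cost-effectiveness plane (bootstrap replicates)")
        fig.tight_layout()
        paths["ce_plane_png"] = outdir / "ce_plane.png"
        fig.savefig(paths["ce_plane_png"], dpi=150)
        plt.close(fig)

        fig, ax = plt.subplots(figsize=(5, 4))
        ax.plot(ceac_points["lambda_eur_per_qaly"], ceac_points["probability"])
        ax.set_ylim(0, 1.02)
        ax.set_xlabel("Willingness to pay (EUR/QALY)")
        ax.set_ylabel("P(cost-effective)")
        ax.set_title("Cost-effectiveness acceptability curve")
        fig.tight_layout()
        paths["ceac_png"] = outdir / "ceac.png"
        fig.savefig(paths["ceac_png"], dpi=150)
        plt.close(fig)
    return paths
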