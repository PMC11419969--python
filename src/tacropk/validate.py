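"""Model validation: subject-level bootstrap, (prediction-corrected) visual
predictive check, and goodness-of-fit tables."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import estimate
from .estimate import FitResult, ModelSpec, _Workspace
from .io import PKEventDataset

__all__ = ["BootstrapResult", "bootstrap", "VPCResult", "vpc", "gof_tables"]


@dataclass
class BootstrapResult:
    """Per-parameter summaries over converged bootstrap refits.

    Subjects (not observations) are the resampling unit, which preserves
    the hierarchical structure of the data.  Failed refits are dropped and
    counted; ``unreliable`` flags a failure fraction above 20 %.
    """

    summary: pd.DataFrame  # parameter, mean, sd, cv_pct, median, p2.5, p97.5
    estimates: pd.DataFrame  # one row per converged resample
    n_requested: int
    n_failed: int
    unreliable: bool

    def ci95(self, parameter: str) -> tuple[float, float]:
        row = self.summary.set_index("parameter").loc[parameter]
        return float(row["p2.5"]), float(row["p97.5"])


def bootstrap(
    data: PKEventDataset,
    spec: ModelSpec,
    n_resamples: int = 1000,
    seed: int = 0,
    start: dict | None = None,
    n_starts: int = 1,
    resample_ids: list | None = None,
) -> BootstrapResult:
    """Resample subjects with replacement, refit, summarise.

    ``start`` (typically the original fit's estimates) warm-starts every
    refit.  ``resample_ids`` forces explicit resamples (used to verify the
    identity-resample contract).  Confidence limits are empirical 2.5/97.5
    percentiles over converged refits.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    rng = np.random.default_rng(seed)
    ids = data.subject_ids
    records = []
    n_failed = 0
    for b in range(n_resamples):
        if resample_ids is not None:
            chosen = resample_ids[b]
        else:
            chosen = [ids[i] for i in rng.integers(0, len(ids), size=len(ids))]
        sample = data.subset(chosen, relabel=True)
        try:
            res = estimate.fit(
                spec, sample, start=start, n_starts=n_starts, seed=seed,
                compute_se=False,
            )
            records.append({"resample": b, **res.params})
        except Exception as err:  # noqa: BLE001 - failed refits dropped, counted
            n_failed += 1
            warnings.warn(f"bootstrap refit {b} failed ({err}); dropped", stacklevel=2)
    estimates = pd.DataFrame(records)
    rows = []
    for name in spec.param_names():
        vals = estimates[name].to_numpy() if name in estimates else np.array([])
        if vals.size:
            rows.append(
                {
                    "parameter": name,
                    "mean": vals.mean(),
                    "sd": vals.std(ddof=1) if vals.size > 1 else 0.0,
                    "cv_pct": 100 * vals.std(ddof=1) / vals.mean()
                    if vals.size > 1 and vals.mean() != 0
                    else np.nan,
                    "median": np.median(vals),
                    "p2.5": np.percentile(vals, 2.5),
                    "p97.5": np.percentile(vals, 97.5),
                }
            )
    unreliable = n_failed > 0.2 * n_resamples
    if unreliable:
        warnings.warn(
            f"{n_failed}/{n_resamples} bootstrap refits failed; summaries unreliable",
            stacklevel=2,
        )
    return BootstrapResult(
        summary=pd.DataFrame(rows),
        estimates=estimates,
        n_requested=n_resamples,
        n_failed=n_failed,
        unreliable=unreliable,
    )


@dataclass
class VPCResult:
    """Binned observed percentiles with simulation-based confidence bands."""

    table: pd.DataFrame  # bin stats: tad_mid, obs_p5/p50/p95, band lo/hi per pct
    prediction_corrected: bool
    n_sim: int
    seed: int

    def fraction_inside(self) -> float:
        """Fraction of observed-percentile points inside their 90 % bands."""
        t = self.table
        inside = 0
        total = 0
        for p in (5, 50, 95):
            total += len(t)
            inside += int(
                ((t[f"obs_p{p}"] >= t[f"sim_p{p}_lo"]) & (t[f"obs_p{p}"] <= t[f"sim_p{p}_hi"])).sum()
            )
        return inside / total


def vpc(
    fit_result: FitResult | None,
    data: PKEventDataset,
    n_sim: int = 1000,
    bins: int = 10,
    prediction_corrected: bool = True,
    seed: int = 0,
    spec: ModelSpec | None = None,
    params: dict | None = None,
    min_bin_size: int = 10,
) -> VPCResult:
    """Visual predictive check under the fitted (or supplied) model.

    Simulates ``n_sim`` replicate datasets with the design, dosing and
    covariates held at their observed values, bins observations by time
    after dose (deciles by default, small bins merged with a logged
    message), and compares observed 5/50/95 percentiles with the 5th-95th
    percentile band of each simulated percentile (a 90 % CI).  Prediction
    correction rescales observations and simulations by the bin-median
    population prediction.
    """
    if fit_result is not None:
        spec = fit_result.spec
        params = fit_result.full_params()
    elif spec is None or params is None:
        raise ValueError("supply either a FitResult or spec+params")
    else:
        params = spec.full_params(params)
    ws = _Workspace(data, spec)
    rng = np.random.default_rng(seed)
    act = spec.active_etas(params)

    zero = np.zeros(ws.S)
    pred = ws.predict(params, zero, zero)[ws.mask]
    obs = ws.y[ws.mask]
    tad = ws.tad[ws.mask]

    # simulate replicates (vectorised over subjects; loop over replicates)
    sims = np.empty((n_sim, obs.size))
    sd_v = np.sqrt(params["omega2_v"]) if "v" in act else 0.0
    sd_cl = np.sqrt(params["omega2_cl"]) if "cl" in act else 0.0
    for r in range(n_sim):
        ev = rng.normal(0.0, sd_v, size=ws.S)
        ec = rng.normal(0.0, sd_cl, size=ws.S)
        f = ws.predict(params, ev, ec)
        w2 = ws._res_var(f, params)
        y = f + rng.normal(0.0, 1.0, size=f.shape) * np.sqrt(w2)
        sims[r] = y[ws.mask]

    # TAD bins: quantile edges, merging small bins with their neighbour
    order = np.argsort(tad, kind="stable")
    edges = np.unique(np.quantile(tad, np.linspace(0, 1, bins + 1)))
    idx = np.clip(np.searchsorted(edges, tad, side="right") - 1, 0, len(edges) - 2)
    # merge undersized bins leftward
    for b in range(len(edges) - 1):
        if (idx == b).sum() and (idx == b).sum() < min_bin_size:
            target = b - 1 if b > 0 else b + 1
            idx[idx == b] = target
    bin_ids = np.unique(idx)

    rows = []
    for b in bin_ids:
        m = idx == b
        if prediction_corrected:
            pc = np.median(pred[m])
            scale = pc / np.maximum(pred[m], 1e-9)
            o = obs[m] * scale
            s = sims[:, m] * scale[None, :]
        else:
            o = obs[m]
            s = sims[:, m]
        row = {"tad_mid": float(np.median(tad[m])), "n": int(m.sum())}
        for p in (5, 50, 95):
            row[f"obs_p{p}"] = float(np.percentile(o, p))
            sim_pct = np.percentile(s, p, axis=1)
            row[f"sim_p{p}_lo"] = float(np.percentile(sim_pct, 5))
            row[f"sim_p{p}_hi"] = float(np.percentile(sim_pct, 95))
            row[f"sim_p{p}_med"] = float(np.percentile(sim_pct, 50))
        rows.append(row)
    table = pd.DataFrame(rows).sort_values("tad_mid").reset_index(drop=True)
    return VPCResult(
        table=table,
        prediction_corrected=prediction_corrected,
        n_sim=n_sim,
        seed=seed,
    )


def gof_tables(fit_result: FitResult, data: PKEventDataset) -> pd.DataFrame:
    """Tidy goodness-of-fit table: DV, PRED (eta=0), IPRED (EBEs), CWRES, TAD.

    Sufficient to regenerate the standard four diagnostic panels
    (DV~IPRED, DV~PRED, CWRES~IPRED, CWRES~TAD).
    """
    out = estimate.predict_observations(
        fit_result.spec, fit_result.full_params(), data, etas=fit_result.ebes
    )
    out["CWRES"] = fit_result.cwres
    return out[["ID", "TIME", "TAD", "DV", "PRED", "IPRED", "CWRES"]]
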