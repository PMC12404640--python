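"""End-to-end orchestration: per-subject processing and group analysis.

Per subject: resolution sweep with stability selection, consensus
partition at the selected gamma, hierarchical boundary-controllability
ranking, mean modularity over the ensemble at the selected gamma, and node
strengths.  Per cohort: the statistical battery comparing controllability
at named target regions between groups and relating it to behavior.

Every report embeds the full run configuration, master seed, and library
versions.  Per-subject results can be cached to disk keyed by a content
hash of the connectome and the relevant configuration, so re-runs are
loaded bit-identically instead of recomputed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .community import gamma_sweep, consensus_partition, subseed
from .controllability import bc_rank, node_strength
from .io import Connectome, resolve_regions
from .stats import (
    fdr_adjust,
    group_summary,
    linear_model,
    ordinal_group_region_model,
    pearson,
    wilcoxon_ranksum,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "SubjectResult", "run_subject", "run_cohort",
           "run_group_analysis", "run_lesioned_control_check"]

DEFAULT_REGIONS = {
    "rPTr": "rh\\.parstriangularis",
    "rPOperc": "rh\\.parsopercularis",
    "rOccipital": "rh\\.lateraloccipital",
}


@dataclass
class RunConfig:
    """All knobs of a pipeline run; serialized into every report."""

    gamma_min: float = 1.0
    gamma_max: float = 4.0
    gamma_step: float = 0.1
    n_opt: int = 100
    seed: int = 0
    regions: dict = field(default_factory=lambda: dict(DEFAULT_REGIONS))
    region_aggregation: str = "first"      # or "mean" over matched parcels
    within_block_order: str = "eigenvector"
    zrand_degenerate: str = "error"
    mad_scale: float = 1.4826
    exact_threshold: int = 8
    zscore_behavior: bool = True
    ordinal_bins: int = 10
    target_region: str = "rPTr"

    def __post_init__(self):
        if self.gamma_min <= 0 or self.gamma_max < self.gamma_min:
            raise ValueError("invalid gamma range")
        if self.n_opt < 2:
            raise ValueError("n_opt must be >= 2")
        if self.region_aggregation not in ("first", "mean"):
            raise ValueError("region_aggregation must be 'first' or 'mean'")
        if self.target_region not in self.regions:
            raise ValueError(f"target_region {self.target_region!r} not in regions")

    @property
    def gamma_grid(self) -> np.ndarray:
        n = int(round((self.gamma_max - self.gamma_min) / self.gamma_step)) + 1
        return np.round(self.gamma_min + self.gamma_step * np.arange(n), 10)

    def subject_cache_key(self, conn: Connectome) -> str:
        relevant = {
            "gamma_min": self.gamma_min, "gamma_max": self.gamma_max,
            "gamma_step": self.gamma_step, "n_opt": self.n_opt,
            "seed": self.seed, "within_block_order": self.within_block_order,
            "zrand_degenerate": self.zrand_degenerate,
        }
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(conn.weights).tobytes())
        h.update(json.dumps(relevant, sort_keys=True).encode())
        return h.hexdigest()[:24]


@dataclass
class SubjectResult:
    """Everything the group analysis needs from one subject."""

    subject_id: str
    group: str
    labels: list[str]
    selected_gamma: float
    mean_zrand: list[float]
    gammas: list[float]
    consensus_assignment: list[int]
    bc_ranks: list[int]
    q_mean: float
    strengths: list[float]

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "SubjectResult":
        return cls(**json.loads(text))


def _subject_seed(config: RunConfig, subject_id: str) -> int:
    h = int.from_bytes(hashlib.sha256(subject_id.encode()).digest()[:4], "big")
    return int(subseed(config.seed, h).generate_state(1)[0] % 2**31)


def run_subject(conn: Connectome, config: RunConfig, cache_dir=None) -> SubjectResult:
    """Sweep -> consensus -> BC ranking -> mean Q -> strengths for one subject."""
    if cache_dir is not None:
        cache = Path(cache_dir) / f"{config.subject_cache_key(conn)}.json"
        if cache.exists():
            logger.info("subject %s: loaded from cache", conn.subject_id)
            return SubjectResult.from_json(cache.read_text())
    seed = _subject_seed(config, conn.subject_id)
    sweep = gamma_sweep(
        conn.weights,
        gamma_grid=config.gamma_grid,
        n_opt=config.n_opt,
        seed=seed,
        zrand_degenerate=config.zrand_degenerate,
    )
    ens = sweep.selected_partitions
    cons = consensus_partition(ens, seed=seed)
    ranking = bc_rank(
        conn.weights,
        gamma=sweep.selected_gamma,
        n_opt=config.n_opt,
        seed=seed,
        within_block_order=config.within_block_order,
    )
    q_mean = float(np.mean([p.q for p in ens]))
    result = SubjectResult(
        subject_id=conn.subject_id,
        group=conn.group,
        labels=list(conn.labels),
        selected_gamma=float(sweep.selected_gamma),
        mean_zrand=[float(v) for v in sweep.mean_zrand],
        gammas=[float(g) for g in sweep.gammas],
        consensus_assignment=[int(c) for c in cons.assignment],
        bc_ranks=[int(r) for r in ranking.rank],
        q_mean=q_mean,
        strengths=[float(s) for s in conn.strengths()],
    )
    if cache_dir is not None:
        Path(cache_dir).mkdir(parents=True, exist_ok=True)
        cache.write_text(result.to_json())
    return result


def run_cohort(connectomes: list[Connectome], config: RunConfig, cache_dir=None) -> list[SubjectResult]:
    """Run every subject; failures are isolated and logged, not fatal."""
    results = []
    for conn in connectomes:
        try:
            results.append(run_subject(conn, config, cache_dir=cache_dir))
        except Exception:
            logger.exception("subject %s failed; continuing", conn.subject_id)
    return results


def _region_value(values: np.ndarray, indices: list[int], aggregation: str) -> float:
    if aggregation == "first":
        return float(values[indices[0]])
    return float(np.mean([values[i] for i in indices]))


def _region_table(results: list[SubjectResult], config: RunConfig) -> pd.DataFrame:
    rows = []
    for res in results:
        regions = resolve_regions(res.labels, config.regions)
        ranks = np.asarray(res.bc_ranks)
        strengths = np.asarray(res.strengths)
        row = {"subject_id": res.subject_id, "group": res.group,
               "q_mean": res.q_mean, "selected_gamma": res.selected_gamma}
        for name, idx in regions.items():
            row[f"bc_{name}"] = _region_value(ranks, idx, config.region_aggregation)
            row[f"strength_{name}"] = _region_value(strengths, idx, config.region_aggregation)
        rows.append(row)
    return pd.DataFrame(rows)


def _versions() -> dict:
    import scipy
    import statsmodels
    return {
        "bcnet": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
    }


def run_group_analysis(
    results: list[SubjectResult],
    behavior: pd.DataFrame,
    config: RunConfig,
) -> dict:
    """The full statistical battery as a single structured report.

    Contents: proportional-odds group-by-region interaction on BC ranks;
    per-region rank-sum tests with FDR correction and group summaries;
    regressions of each behavioral measure on BC at the target region
    (outcomes z-scored per config, BC entered raw); lesion-volume and
    second-region covariate models; correlations of BC with lesion volume,
    homotope damage, node strength, and modularity.
    """
    region_names = list(config.regions)
    target = config.target_region
    table = _region_table(results, config)
    n_pwa = int((table["group"] == "PWA").sum())
    n_ctl = int((table["group"] == "control").sum())
    if min(n_pwa, n_ctl) < 2:
        raise ValueError("need at least 2 subjects per group")

    report: dict = {"n_pwa": n_pwa, "n_controls": n_ctl}

    # ordinal group x region interaction
    long = table.melt(
        id_vars=["subject_id", "group"],
        value_vars=[f"bc_{r}" for r in region_names],
        var_name="region", value_name="bc_rank",
    )
    long["region"] = long["region"].str.removeprefix("bc_")
    try:
        ordinal = ordinal_group_region_model(
            long.rename(columns={"subject_id": "subject"}),
            reference_region=target, n_bins=config.ordinal_bins,
        )
        report["ordinal_interaction"] = {
            "reference_region": ordinal.reference_region,
            "contrasts": ordinal.contrasts,
            "converged": ordinal.converged,
            "loglik": ordinal.loglik,
        }
    except Exception as exc:  # separation / non-convergence: report, don't die
        logger.exception("ordinal model failed")
        report["ordinal_interaction"] = {"error": str(exc)}

    # per-region rank-sum tests with FDR, plus group summaries
    is_pwa = table["group"] == "PWA"
    wil = {}
    raw_ps = []
    for r in region_names:
        res = wilcoxon_ranksum(
            table.loc[is_pwa, f"bc_{r}"], table.loc[~is_pwa, f"bc_{r}"],
            exact_threshold=config.exact_threshold,
        )
        summ = group_summary(table[f"bc_{r}"], table["group"], mad_scale=config.mad_scale)
        wil[r] = {"w": res.w, "p_raw": res.p_raw, "method": res.method,
                  "summary": summ.groups}
        raw_ps.append(res.p_raw)
    for r, p_adj in zip(region_names, fdr_adjust(raw_ps)):
        wil[r]["p_fdr"] = float(p_adj)
    report["wilcoxon_by_region"] = wil

    # behavioral regressions within PWA
    pwa = table[is_pwa].merge(behavior, on="subject_id", how="inner")
    bc_t = pwa[f"bc_{target}"]
    models = {}
    for outcome in ("wab_aq", "pnt_accuracy", "sem_err_prop", "phon_err_prop"):
        try:
            fit = linear_model(
                pwa[outcome], pd.DataFrame({"bc": bc_t}),
                zscore_y=config.zscore_behavior,
            )
            models[outcome] = _reg_dict(fit, "bc")
        except ValueError as exc:
            models[outcome] = {"error": str(exc)}
    report["behavior_models"] = models

    # covariate and control-site follow-ups for the phonological outcome
    followups = {}
    try:
        fit = linear_model(
            pwa["phon_err_prop"],
            pd.DataFrame({"bc": bc_t, "tlv": pwa["tlv"]}),
            zscore_y=config.zscore_behavior,
        )
        followups["phon_tlv_covariate"] = _reg_dict(fit, "bc")
    except ValueError as exc:
        followups["phon_tlv_covariate"] = {"error": str(exc)}
    second = next((r for r in region_names if r != target), None)
    if second is not None:
        try:
            fit = linear_model(
                pwa["phon_err_prop"], pd.DataFrame({"bc": pwa[f"bc_{second}"]}),
                zscore_y=config.zscore_behavior,
            )
            followups[f"phon_{second}"] = _reg_dict(fit, "bc")
            fit = linear_model(
                pwa["phon_err_prop"],
                pd.DataFrame({"bc_target": bc_t, "bc_second": pwa[f"bc_{second}"]}),
                zscore_y=config.zscore_behavior,
            )
            followups["phon_joint_two_region"] = _reg_dict(fit, "bc_target")
        except ValueError as exc:
            followups["phon_second_region"] = {"error": str(exc)}
    report["followup_models"] = followups

    # correlations: lesion volume, homotope damage, strength, modularity
    corrs = {}
    for name, x, y in [
        ("bc_vs_tlv", bc_t, pwa["tlv"]),
        ("bc_vs_lptr_damage", bc_t, pwa["lptr_damage"]),
        ("bc_vs_strength_pwa", bc_t, pwa[f"strength_{target}"]),
        ("bc_vs_modularity", bc_t, pwa["q_mean"]),
    ]:
        try:
            r, p, df = pearson(x, y)
            corrs[name] = {"r": r, "p": p, "df": df}
        except ValueError as exc:
            corrs[name] = {"error": str(exc)}
    ctl = table[~is_pwa]
    try:
        r, p, df = pearson(ctl[f"bc_{target}"], ctl[f"strength_{target}"])
        corrs["bc_vs_strength_controls"] = {"r": r, "p": p, "df": df}
    except ValueError as exc:
        corrs["bc_vs_strength_controls"] = {"error": str(exc)}
    report["correlations"] = corrs

    try:
        fit = linear_model(
            pwa["phon_err_prop"],
            pd.DataFrame({"bc": bc_t, "modularity": pwa["q_mean"]}),
            zscore_y=config.zscore_behavior,
        )
        report["phon_modularity_covariate"] = _reg_dict(fit, "bc")
    except ValueError as exc:
        report["phon_modularity_covariate"] = {"error": str(exc)}

    report["provenance"] = {
        "config": asdict(config),
        "seed": config.seed,
        "versions": _versions(),
    }
    return report


def _reg_dict(fit, key_term: str) -> dict:
    d = {
        "r2": fit.r2, "f": fit.f_stat, "df1": fit.df1, "df2": fit.df2,
        "f_p": fit.f_p, "n": fit.n, "n_dropped": fit.n_dropped,
        "terms": fit.terms,
    }
    d["beta"] = fit.terms[key_term]["beta"]
    d["t"] = fit.terms[key_term]["t"]
    d["p"] = fit.terms[key_term]["p"]
    return d


def run_lesioned_control_check(
    controls: list[Connectome],
    lesion_spec,
    config: RunConfig,
    cache_dir=None,
) -> dict:
    """Network-level lesion sensitivity check on control subjects.

    Each control connectome is lesioned per ``lesion_spec`` (a
    ``SyntheticCohortSpec`` whose lesion block applies), both versions run
    through the subject pipeline, and controllability at the target region
    is compared pre vs post with the rank-sum test.
    """
    from .synthetic import apply_lesion

    if len(controls) < 2:
        raise ValueError("need at least 2 control subjects")
    pre_vals, post_vals = [], []
    for i, conn in enumerate(controls):
        lesioned, _ = apply_lesion(conn, lesion_spec, subseed(config.seed, 777, i))
        lesioned.subject_id = conn.subject_id + "_lesioned"
        res_pre = run_subject(conn, config, cache_dir=cache_dir)
        res_post = run_subject(lesioned, config, cache_dir=cache_dir)
        for res, acc in ((res_pre, pre_vals), (res_post, post_vals)):
            idx = resolve_regions(res.labels, config.regions)[config.target_region]
            acc.append(_region_value(np.asarray(res.bc_ranks), idx,
                                     config.region_aggregation))
    res = wilcoxon_ranksum(pre_vals, post_vals, exact_threshold=config.exact_threshold)
    return {
        "w": res.w, "p": res.p_raw, "method": res.method,
        "n_pairs": len(controls),
        "median_pre": float(np.median(pre_vals)),
        "median_post": float(np.median(post_vals)),
        "provenance": {"config": asdict(config), "versions": _versions()},
    }
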