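"""End-to-end orchestration: synthetic data -> MSN -> contrasts -> spins -> PLS.

Every stochastic stage receives a seed derived deterministically from the
master seed and the stage name (SHA-256 of ``"<seed>:<stage>"``), so adding
a stage never perturbs earlier stages' randomness and fixed-seed reruns
are byte-identical.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .msn import cohort_strengths, group_mean_strength, regional_feature_table, zscore_features
from .parcellation import Parcellation, make_parcellation
from .pls import run_pls_analysis
from .spin import build_spin_ensemble, spin_test
from .stats import (
    RegionalStatMap,
    compare_global_ms,
    fit_regional_contrast,
    frequency_correlation,
    jaccard_flags,
    network_contrast,
)
from .synthetic import (
    draw_regional_profile,
    make_effect_map,
    simulate_expression,
    simulate_morphometry,
)

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Synthetic-cohort parameters default to the study conditions the
    pipeline emulates: two groups of 24 subjects, 308 regions (152 left),
    7 features, 66 genes.
    """

    seed: int = 0
    out_dir: str = "msn_run"
    # synthetic block
    n_regions: int = 308
    n_left: int = 152
    n_per_group: int = 24
    n_genes: int = 66
    n_affected: int = 20
    effect_scale: float = 0.0
    effect_magnitude: float = 1.0
    noise_sd: float = 0.55
    autocorr_length: float = 0.5
    profile_length_scale: float = 0.2
    n_planted_genes: int = 0
    association_strength: float = 0.0
    with_tiv: bool = True
    # analysis switches
    msn_method: str = "pearson"
    n_spins: int = 1000
    n_perm: int = 1000
    n_boot: int = 1000
    alpha: float = 0.05
    sidedness: str = "two"
    # inputs: if set, load these instead of simulating
    parcellation_path: str | None = None
    morphometry_path: str | None = None
    subjects_path: str | None = None
    expression_path: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        flat = {}
        for key, val in raw.items():
            if key == "synthetic" and isinstance(val, dict):
                flat.update(val)
            else:
                flat[key] = val
        unknown = set(flat) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**flat)


@dataclass
class RunManifest:
    """Provenance of one run: config echo, checksums, wall-clock, warnings."""

    config: dict
    version: str
    checksums: dict = field(default_factory=dict)
    wall_clock: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    skipped: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def summarize_directionality(stat_map: RegionalStatMap, mean_ms: np.ndarray) -> dict:
    """Quadrant split of the t-map against a mean-MS map.

    ``pct_dediff``: % regions with t > 0 and mean MS < 0 (regions normally
    differentiated that move toward the cortical average in users —
    de-differentiation); ``pct_diff``: % with t < 0 and mean MS > 0
    (normally similar regions becoming differentiated / uncoupled);
    ``r_mean_vs_t``: Pearson r between the two maps.
    """
    mean_ms = np.asarray(mean_ms, dtype=float)
    if mean_ms.shape != stat_map.t.shape:
        raise ValueError("mean_ms length must match the stat map")
    R = stat_map.n_regions
    pct_dediff = 100.0 * np.sum((stat_map.t > 0) & (mean_ms < 0)) / R
    pct_diff = 100.0 * np.sum((stat_map.t < 0) & (mean_ms > 0)) / R
    if stat_map.t.std() == 0 or mean_ms.std() == 0:
        r = float("nan")  # correlation undefined for a constant map
    else:
        r = float(np.corrcoef(mean_ms, stat_map.t)[0, 1])
    return {"pct_dediff": float(pct_dediff), "pct_diff": float(pct_diff), "r_mean_vs_t": r}


class StageError(RuntimeError):
    """An error inside a named pipeline stage; partial outputs are kept."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig, return_state: bool = False):
    """Execute the full pipeline and write all stage outputs plus manifest.

    Stages: simulate (or load) -> MSN/strengths -> regional, network,
    global and attendance contrasts (+ TIV replication and CT model) ->
    spin anchoring of the t-map against mean control MS -> left-hemisphere
    PLS against gene expression. ``n_spins=0`` skips the spin stages;
    ``n_perm=0``/``n_boot=0`` skip the corresponding PLS assessments.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict(config), version=__version__)
    partial_marker = out / ".partial"
    partial_marker.write_text("run in progress\n")

    import warnings as _warnings

    def _run_stage(name, fn):
        t0 = time.perf_counter()
        try:
            with _warnings.catch_warnings(record=True) as caught:
                _warnings.simplefilter("always")
                result = fn()
            for w in caught:
                manifest.warnings.append(f"{name}: {w.message}")
        except Exception as exc:  # noqa: BLE001 - rewrap with stage context
            raise StageError(name, exc) from exc
        manifest.wall_clock[name] = round(time.perf_counter() - t0, 3)
        return result

    state: dict = {}

    def simulate():
        if config.parcellation_path:
            parc = mio.read_parcellation(config.parcellation_path)
            table = mio.read_morphometry(config.morphometry_path, config.subjects_path)
            expr = mio.read_expression(config.expression_path) if config.expression_path else None
            effect = np.zeros(parc.n_regions)
        else:
            s = stage_seed(config.seed, "simulate")
            parc = make_parcellation(config.n_regions, config.n_left, seed=s)
            profile = draw_regional_profile(
                parc, seed=s + 1, profile_length_scale=config.profile_length_scale
            )
            effect = (
                make_effect_map(
                    parc,
                    config.n_affected,
                    seed=s + 2,
                    magnitude=config.effect_magnitude,
                    profile=profile,
                )
                if config.effect_scale > 0 and config.n_affected > 0
                else np.zeros(parc.n_regions)
            )
            table, _ = simulate_morphometry(
                parc,
                n_per_group=config.n_per_group,
                effect_map=effect,
                effect_scale=config.effect_scale,
                noise_sd=config.noise_sd,
                covariate_model={"tiv": config.with_tiv},
                seed=s + 3,
                profile=profile,
            )
            n_planted = config.n_planted_genes
            planted_pos = np.arange(n_planted // 2)
            planted_neg = np.arange(n_planted // 2, n_planted)
            expr = simulate_expression(
                parc,
                n_genes=config.n_genes,
                autocorr_length=config.autocorr_length,
                effect_map=effect,
                planted_pos=planted_pos,
                planted_neg=planted_neg,
                association_strength=config.association_strength,
                seed=s + 3,
            )
            mio.write_parcellation(parc, out / "parcellation.tsv")
            mio.write_morphometry(table, out / "morphometry.tsv", out / "subjects.tsv")
            if expr is not None:
                mio.write_expression(expr, out / "expression.tsv")
        state.update(parc=parc, table=table, expr=expr, effect=effect)

    _run_stage("simulate", simulate)

    def msn_stage():
        std = zscore_features(state["table"])
        strengths = cohort_strengths(std, method=config.msn_method)
        mio.write_strengths(strengths, out / "strengths.tsv")
        state.update(std=std, strengths=strengths)

    _run_stage("msn", msn_stage)

    def contrast_stage():
        parc, table = state["parc"], state["table"]
        strengths = state["strengths"]
        subjects = table.subjects
        sm = fit_regional_contrast(strengths, subjects, alpha=config.alpha)
        sm.to_frame().to_csv(out / "regional_contrast.tsv", sep="\t", index=False, float_format="%.17g")
        nets = pd.concat(
            [
                network_contrast(strengths, subjects, parc, atlas="yeo7", alpha=config.alpha),
                network_contrast(strengths, subjects, parc, atlas="von_economo", alpha=config.alpha),
            ]
        )
        nets.to_csv(out / "network_contrast.tsv", sep="\t", index=False, float_format="%.17g")
        global_tests = compare_global_ms(strengths, subjects)

        summary = {"global": global_tests}
        if config.with_tiv and subjects["tiv"].notna().all():
            sm_tiv = fit_regional_contrast(
                strengths, subjects, extra_covariates=("tiv",), alpha=config.alpha
            )
            summary["jaccard_tiv"] = jaccard_flags(sm.significant, sm_tiv.significant)
            summary["r_t_main_vs_tiv"] = float(np.corrcoef(sm.t, sm_tiv.t)[0, 1])
        # cortical-thickness model with mean cross-hemispheric CT as nuisance
        ct = regional_feature_table(table, "CT")
        mean_ct = ct.to_numpy().mean(axis=1)
        sm_ct = fit_regional_contrast(ct, subjects, response="ct", mean_ct=mean_ct, alpha=config.alpha)
        sm_ct.to_frame().to_csv(out / "ct_contrast.tsv", sep="\t", index=False, float_format="%.17g")
        if sm.significant.any():
            freq = frequency_correlation(strengths, subjects, sm)
            freq.to_csv(out / "frequency_correlation.tsv", sep="\t", index=False, float_format="%.17g")
            state["freq"] = freq
        else:
            manifest.skipped.append("frequency_correlation: no FDR-significant regions")
        mean_ms_control = group_mean_strength(strengths, subjects, "control")
        summary["directionality"] = summarize_directionality(sm, mean_ms_control)
        state.update(stat_map=sm, mean_ms_control=mean_ms_control, summary=summary)

    _run_stage("contrast", contrast_stage)

    def spin_stage():
        if config.n_spins <= 0:
            manifest.skipped.append("spin: n_spins = 0")
            return
        parc = state["parc"]
        ens = build_spin_ensemble(parc, config.n_spins, seed=stage_seed(config.seed, "spin"))
        res = spin_test(
            state["mean_ms_control"], state["stat_map"].t, ens, sidedness=config.sidedness
        )
        np.savetxt(out / "spin_null_r.tsv", res.null_r, fmt="%.17g")
        state["summary"]["spin_mean_ms_vs_t"] = {
            "r": res.r_observed,
            "p_spin": res.p_spin,
            "n_spins": config.n_spins,
        }
        state["spin_ensemble"] = ens

    _run_stage("spin", spin_stage)

    def pls_stage():
        expr, parc = state["expr"], state["parc"]
        if expr is None:
            manifest.skipped.append("pls: no expression data")
            return
        if config.n_perm <= 0 or config.n_boot <= 0:
            manifest.skipped.append("pls: n_perm or n_boot = 0")
            return
        left = parc.left_mask
        y = state["stat_map"].t[left]
        ens = None
        if config.n_spins > 0:
            ens = build_spin_ensemble(
                parc, config.n_spins, seed=stage_seed(config.seed, "pls_spin"), left_only=True
            )
        res = run_pls_analysis(
            expr,
            y,
            parc,
            ensemble=ens,
            n_perm=config.n_perm,
            n_boot=config.n_boot,
            seed=stage_seed(config.seed, "pls"),
        )
        genes = pd.DataFrame(
            {
                "gene": res.gene_symbols,
                "weight": res.weights,
                "boot_z": res.boot_z,
                "sig_pos": [g in set(res.sig_pos) for g in res.gene_symbols],
                "sig_neg": [g in set(res.sig_neg) for g in res.gene_symbols],
            }
        )
        genes.to_csv(out / "pls_genes.tsv", sep="\t", index=False, float_format="%.17g")
        state["summary"]["pls"] = {
            "varexp": res.varexp,
            "p_perm": res.p_perm,
            "r_spatial": res.r_spatial,
            "p_spin_spatial": res.p_spin_spatial,
            "n_sig_pos": len(res.sig_pos),
            "n_sig_neg": len(res.sig_neg),
            "sig_pos": res.sig_pos,
            "sig_neg": res.sig_neg,
        }
        state["pls"] = res

    _run_stage("pls", pls_stage)

    mio.write_json(state["summary"], out / "summary.json")
    for f in sorted(out.iterdir()):
        if f.is_file() and f.name not in ("manifest.json", ".partial"):
            manifest.checksums[f.name] = _sha256(f)
    mio.write_json(manifest.to_dict(), out / "manifest.json")
    partial_marker.unlink(missing_ok=True)
    if return_state:
        return manifest, state
    return manifest
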