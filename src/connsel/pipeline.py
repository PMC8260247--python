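"""End-to-end orchestration: simulate -> GLM -> connectivity -> selection
-> decoding -> group statistics, driven by one validated config.

Outputs are tidy CSV tables (fold-level and fold-averaged decoding,
ANOVA terms, matched-activation results with retained-subject counts,
tSNR comparison), optional searchlight group maps, and a JSON manifest
(config, hash, derived seeds, package versions) sufficient to re-run
any stage in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import selection as sel
from .decoding import (
    SubjectAnalysis,
    decode_all,
    fold_average,
    matched_decoding_table,
    tsnr_table,
)
from .io import export_map_nifti
from .layout import (
    RegionLayout,
    RegionSpec,
    compact_searchlight_layout,
    compact_two_region_layout,
    make_layout,
    six_region_layout,
    searchlight_layout,
    two_region_layout,
)
from .searchlight import goodseed_maps, neighborhoods
from .simulate import EffectSpec, simulate_cohort
from .stats import bonferroni_threshold, paired_t, rm_anova, signflip_group_map

log = logging.getLogger("connsel")

_LAYOUTS = {
    "six_region": six_region_layout,
    "two_region": two_region_layout,
    "compact_two_region": compact_two_region_layout,
    "searchlight": searchlight_layout,
    "compact_searchlight": compact_searchlight_layout,
}

_EFFECT_KEYS = {
    "coupling_strength", "frac_informative", "pattern_snr", "activation_gain",
    "noise_sd", "activation_coupled", "pattern_carrier",
}
_TOP_KEYS = {
    "n_subjects", "n_runs", "effect", "layout", "layout_specs", "grid_dims",
    "k", "n_perm", "n_draws", "seed", "out_dir", "analyses", "hp_cutoff_seconds",
    "matched_thresholds", "searchlight_comparisons",
}
_ANALYSIS_KEYS = {"main", "matched", "snr", "searchlight"}


@dataclass
class PipelineConfig:
    """Validated, fully defaulted pipeline configuration."""

    n_subjects: int = 20
    n_runs: int = 6
    effect: EffectSpec = field(default_factory=EffectSpec)
    layout_name: str = "six_region"
    layout_specs: list[RegionSpec] | None = None
    grid_dims: tuple[int, int, int] | None = None
    k: int = sel.DEFAULT_K
    n_perm: int = 10000
    n_draws: int = 10000
    hp_cutoff_seconds: float = 256.0
    seed: int = 0
    out_dir: str = "connsel_out"
    analyses: dict[str, bool] = field(
        default_factory=lambda: {"main": True, "matched": True, "snr": True,
                                 "searchlight": True})
    matched_thresholds: tuple[str, ...] = sel.MATCH_THRESHOLDS
    searchlight_comparisons: int = 1  # comparisons per region to map

    def make_layout(self) -> RegionLayout:
        if self.layout_specs is not None:
            return make_layout(self.grid_dims, self.layout_specs)
        return _LAYOUTS[self.layout_name]()

    def to_dict(self) -> dict:
        d = {
            "n_subjects": self.n_subjects,
            "n_runs": self.n_runs,
            "effect": {k: v for k, v in asdict(self.effect).items() if k != "seed"},
            "layout": self.layout_name,
            "k": self.k,
            "n_perm": self.n_perm,
            "n_draws": self.n_draws,
            "hp_cutoff_seconds": self.hp_cutoff_seconds,
            "seed": self.seed,
            "out_dir": self.out_dir,
            "analyses": dict(self.analyses),
            "matched_thresholds": list(self.matched_thresholds),
            "searchlight_comparisons": self.searchlight_comparisons,
        }
        if self.layout_specs is not None:
            d["grid_dims"] = list(self.grid_dims)
            d["layout_specs"] = [asdict(s) for s in self.layout_specs]
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def validate_config(raw: dict | None = None) -> PipelineConfig:
    """Fill defaults and reject inconsistent or unknown settings.

    An empty config yields the full default configuration (six runs,
    k = 100, 10,000 matched draws and permutations, all analyses on).
    """
    raw = dict(raw or {})
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    effect_raw = dict(raw.pop("effect", {}))
    bad = set(effect_raw) - _EFFECT_KEYS
    if bad:
        raise ValueError(f"unknown effect keys: {sorted(bad)}")
    analyses_raw = dict(raw.pop("analyses", {}))
    bad = set(analyses_raw) - _ANALYSIS_KEYS
    if bad:
        raise ValueError(f"unknown analysis toggles: {sorted(bad)}")

    cfg = PipelineConfig(effect=EffectSpec(**effect_raw))
    cfg.analyses.update(analyses_raw)
    if "layout" in raw:
        name = raw.pop("layout")
        if name not in _LAYOUTS:
            raise ValueError(f"unknown layout {name!r}")
        cfg.layout_name = name
    if "layout_specs" in raw:
        specs = []
        for s in raw.pop("layout_specs"):
            if isinstance(s, dict):
                s = RegionSpec(s["name"], tuple(s["center"]), float(s["radius"]),
                               s["role"], s["category"])
            specs.append(s)
        cfg.layout_specs = specs
        cfg.grid_dims = tuple(raw.pop("grid_dims"))
    for key in ("n_subjects", "n_runs", "k", "n_perm", "n_draws", "seed",
                "searchlight_comparisons"):
        if key in raw:
            setattr(cfg, key, int(raw.pop(key)))
    if "hp_cutoff_seconds" in raw:
        cfg.hp_cutoff_seconds = float(raw.pop("hp_cutoff_seconds"))
    if "out_dir" in raw:
        cfg.out_dir = str(raw.pop("out_dir"))
    if "matched_thresholds" in raw:
        th = tuple(raw.pop("matched_thresholds"))
        bad = set(th) - set(sel.MATCH_THRESHOLDS)
        if bad:
            raise ValueError(f"unknown matched thresholds: {sorted(bad)}")
        cfg.matched_thresholds = th

    layout = cfg.make_layout()
    smallest = min(layout.regions[r].size for r in layout.target_regions())
    if 2 * cfg.k > smallest:
        raise ValueError(
            f"2k = {2 * cfg.k} exceeds the smallest target region "
            f"({smallest} voxels)")
    if cfg.n_runs != 6:
        raise ValueError("the split scheme requires 6 runs")
    return cfg


def _category_anova(avg: pd.DataFrame, modes: tuple[str, str]) -> pd.DataFrame:
    """Per-category three-way RM-ANOVA (mode x region x comparison)."""
    rows = []
    for cat, sub in avg[avg["mode"].isin(modes)].groupby("category", observed=True):
        if sub["region"].nunique() < 2 or sub["comparison"].nunique() < 2:
            factors = [f for f in ("mode", "region", "comparison")
                       if sub[f].nunique() > 1]
        else:
            factors = ["mode", "region", "comparison"]
        try:
            res = rm_anova(sub, "accuracy", factors)
        except ValueError as exc:
            log.warning("ANOVA skipped for %s: %s", cat, exc)
            continue
        for term, vals in res.table.iterrows():
            rows.append((cat, term, vals["F"], vals["df_num"], vals["df_den"],
                         vals["p"], vals["partial_eta_sq"], res.n_subjects))
    return pd.DataFrame(
        rows, columns=["category", "term", "F", "df_num", "df_den", "p",
                       "partial_eta_sq", "n_subjects"])


def _posthoc_table(avg: pd.DataFrame, mode_a: str, mode_b: str) -> pd.DataFrame:
    """Region-wise paired t (mode_a vs mode_b), Bonferroni threshold attached."""
    rows = []
    cells = list(avg.groupby(["region", "comparison"], observed=True))
    alpha_corr = bonferroni_threshold(0.05, max(len(cells), 1))
    for (region, comp), sub in cells:
        wide = sub.pivot(index="subject", columns="mode", values="accuracy")
        if mode_a not in wide or mode_b not in wide:
            continue
        try:
            t, df, p = paired_t(wide[mode_a], wide[mode_b])
        except ValueError:
            continue
        rows.append((region, comp, t, df, p, alpha_corr, p < alpha_corr))
    return pd.DataFrame(
        rows, columns=["region", "comparison", "t", "df", "p",
                       "bonferroni_alpha", "significant"])


def run_pipeline(config: PipelineConfig, write_outputs: bool = True) -> dict:
    """Run every enabled stage; return (and optionally write) the report.

    Subjects are simulated and analyzed one at a time so memory stays
    bounded; per-subject GLM and connectivity products are computed once
    and shared across the main, matched, SNR and searchlight stages.
    """
    t0 = time.time()
    out = Path(config.out_dir)
    if write_outputs:
        out.mkdir(parents=True, exist_ok=True)
    layout = config.make_layout()
    scheme = sel.make_split_scheme(config.n_runs, seed=config.seed)
    cohort = simulate_cohort(
        config.n_subjects, config.effect, seed=config.seed, layout=layout,
        n_runs=config.n_runs)

    report: dict = {"tables": {}, "maps": {}}
    matched_seed = int(
        np.random.SeedSequence([config.seed, 1]).generate_state(1)[0] % (2**31))
    perm_seed = int(
        np.random.SeedSequence([config.seed, 2]).generate_state(1)[0] % (2**31))

    fold_tables, matched_tables, retention_tables, tsnr_tables = [], [], [], []
    sl_diffs: dict[tuple[str, str], list[np.ndarray]] = {}
    sl_centers: dict[tuple[str, str], np.ndarray] = {}
    nb = None
    if config.analyses.get("searchlight"):
        nb = neighborhoods(layout)

    for i_sub, ds in enumerate(cohort):
        t_sub = time.time()
        sa = SubjectAnalysis(ds, hp_cutoff_seconds=config.hp_cutoff_seconds)
        cache = {ds.subject_id: sa}
        sub_matched_seed = int(
            np.random.SeedSequence([matched_seed, i_sub]).generate_state(1)[0]
            % (2**31))
        if config.analyses.get("main", True):
            fold_tables.append(decode_all([ds], scheme, k=config.k, analyses=cache))
        if config.analyses.get("matched"):
            for th in config.matched_thresholds:
                tab, ret = matched_decoding_table(
                    [ds], scheme, threshold_mode=th, n_draws=config.n_draws,
                    seed=sub_matched_seed, k=config.k, analyses=cache)
                tab["threshold"] = th
                matched_tables.append(tab)
                retention_tables.append(ret)
        if config.analyses.get("snr"):
            tsnr_tables.append(tsnr_table([ds], scheme, k=config.k, analyses=cache))
        if config.analyses.get("searchlight"):
            from .decoding import comparisons_for

            for region in layout.target_regions():
                comps = comparisons_for(layout.categories[region])
                for comp in comps[: config.searchlight_comparisons]:
                    m = goodseed_maps(ds, region, comp, analysis=sa,
                                      neighborhood_idx=nb)
                    key = (region, "v".join(comp))
                    sl_diffs.setdefault(key, []).append(m.difference())
                    sl_centers[key] = m.centers
        log.info("subject %s analyzed in %.1fs", ds.subject_id, time.time() - t_sub)
        del sa, cache

    # ---- group statistics --------------------------------------------
    if fold_tables:
        folds = pd.concat(fold_tables, ignore_index=True)
        avg = fold_average(folds)
        report["tables"]["decoding_folds"] = folds
        report["tables"]["decoding"] = avg
        report["tables"]["anova_most_vs_least"] = _category_anova(
            avg, (sel.MOST_CONNECTED, sel.LEAST_CONNECTED))
        report["tables"]["anova_most_vs_activated"] = _category_anova(
            avg, (sel.MOST_CONNECTED, sel.MOST_ACTIVATED))
        report["tables"]["posthoc_most_vs_least"] = _posthoc_table(
            avg, sel.MOST_CONNECTED, sel.LEAST_CONNECTED)
    if matched_tables:
        mtab = pd.concat(matched_tables, ignore_index=True)
        report["tables"]["matched_folds"] = mtab
        ret = pd.concat(retention_tables, ignore_index=True)
        report["tables"]["matched_retention"] = ret
        mrows = []
        for th, sub in mtab.groupby("threshold", observed=True):
            mavg = fold_average(sub.drop(columns="threshold"))
            counts = (
                mavg.pivot_table(index=["region", "comparison"], columns="mode",
                                 values="subject", aggfunc="nunique")
                .min(axis=1).rename("n_subjects").reset_index())
            counts["threshold"] = th
            mrows.append(counts)
            an = _category_anova(mavg, (sel.MATCHED_STRONG, sel.MATCHED_WEAK))
            an["threshold"] = th
            report["tables"][f"anova_matched_{th}"] = an
        report["tables"]["matched_subject_counts"] = pd.concat(mrows, ignore_index=True)
    if tsnr_tables:
        ts = pd.concat(tsnr_tables, ignore_index=True)
        report["tables"]["tsnr"] = ts
        wide_all = []
        for region, sub in ts.groupby("region", observed=True):
            wide = sub.pivot(index="subject", columns="mode", values="tsnr")
            t, df, p = paired_t(wide[sel.MOST_CONNECTED], wide[sel.LEAST_CONNECTED])
            wide_all.append((region, t, df, p))
        report["tables"]["tsnr_posthoc"] = pd.DataFrame(
            wide_all, columns=["region", "t", "df", "p"])

    for key, diffs in sl_diffs.items():
        region, comp = key
        centers = sl_centers[key]
        n_vox = layout.n_voxels
        d = np.zeros((len(diffs), n_vox))
        m = np.zeros(n_vox, dtype=bool)
        m[centers] = True
        for i, vals in enumerate(diffs):
            d[i, centers] = np.nan_to_num(vals, nan=0.0)
        gm = signflip_group_map(
            d, grid_dims=layout.grid_dims, n_perm=config.n_perm,
            seed=perm_seed, mask=m)
        report["maps"][f"searchlight_{region}_{comp}"] = gm

    # ---- outputs ------------------------------------------------------
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "derived_seeds": {"matched": matched_seed, "permutation": perm_seed},
        "versions": {
            "connsel": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "elapsed_seconds": round(time.time() - t0, 2),
    }
    report["manifest"] = manifest
    if write_outputs:
        for name, tab in report["tables"].items():
            tab.to_csv(out / f"{name}.csv", index=False)
        for name, gm in report["maps"].items():
            export_map_nifti(gm.z, layout.grid_dims, out / f"{name}_z.nii")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return report
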