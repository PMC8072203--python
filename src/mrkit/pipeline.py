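"""Workflow orchestration: forward MR, reverse MR, and the BMA stage.

A single structured YAML config drives the whole analysis. Each run writes a
report bundle of tab-delimited tables plus a machine-readable JSON audit
sidecar; every table carries the config hash and master seed in a header
comment so any number in any report is traceable to the exact configuration
that produced it. Runs with equal config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gwas_io, harmonize, mrbma, multiple_testing, uvmr
from .presso import presso as _run_presso
from .gwas_io import REGION_PRESETS

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "load_config", "run_forward", "run_reverse", "run_bma"]


@dataclass(slots=True)
class RunConfig:
    exposure_files: list[str]
    outcome_file: str
    out_dir: str
    exposure_dialect: dict[str, str] | None = None
    outcome_dialect: dict[str, str] | None = None
    direction: str = "forward"  # forward | reverse | both
    methods: list[str] = field(default_factory=lambda: ["ivw", "egger", "wmedian"])
    ivw_model: str = "multiplicative-re"
    palindrome_mode: str = "assume-forward"
    maf_noninfer: float = 0.40
    p_max: float = 5e-8
    f_min: float = 10.0
    maf_min: float = 0.01
    min_snps: int = 3
    region_exclusions: list = field(default_factory=list)  # preset names or [chrom, start, end]
    exclude_outcome_gws: bool = True
    clump_r2: float = 0.001
    ld_matrix_file: str | None = None
    proxy_file: str | None = None
    presso: bool = False
    presso_nsim: int = 1000
    wmedian_nboot: int = 5000
    bma_prior_p: float = 0.1
    bma_sigma2: float = 0.25
    bma_mode: str = "auto"
    bma_z: int = 10000
    rg_file: str | None = None
    rg_threshold: float = 0.95
    corr_file: str | None = None  # for the effective-tests threshold
    alpha: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for f in [*self.exposure_files, self.outcome_file]:
            if not Path(f).exists():
                raise FileNotFoundError(f"config references absent file: {f}")
        for f in (self.ld_matrix_file, self.proxy_file, self.rg_file, self.corr_file):
            if f is not None and not Path(f).exists():
                raise FileNotFoundError(f"config references absent file: {f}")
        if self.direction not in ("forward", "reverse", "both"):
            raise ValueError(f"unknown direction {self.direction!r}")

    def hash(self) -> str:
        """Hash of the analytic settings (output location excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def load_config(path: str) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg


def _write_tsv(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg.hash()} seed={cfg.seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def _resolve_regions(cfg: RunConfig) -> list[tuple[str, int, int]]:
    out = []
    for r in cfg.region_exclusions:
        if isinstance(r, str):
            if r not in REGION_PRESETS:
                raise ValueError(f"unknown region preset {r!r}; known: {list(REGION_PRESETS)}")
            out.append(REGION_PRESETS[r])
        else:
            chrom, start, end = r
            out.append((str(chrom), int(start), int(end)))
    return out


def _exposure_id(path: str) -> str:
    return Path(path).stem


def _select_and_filter(
    assocs: list[gwas_io.VariantAssociation],
    exposure_id: str,
    outcome: list[gwas_io.VariantAssociation],
    cfg: RunConfig,
    ld_matrix: pd.DataFrame | None,
    do_clump: bool,
) -> gwas_io.InstrumentSet:
    if do_clump and ld_matrix is not None:
        assocs = gwas_io.clump(assocs, ld_matrix, r2_max=cfg.clump_r2)
    inst = gwas_io.select_instruments(
        assocs,
        exposure_id=exposure_id,
        p_max=cfg.p_max,
        f_min=cfg.f_min,
        maf_min=cfg.maf_min,
        min_snps=cfg.min_snps,
    )
    if do_clump and ld_matrix is not None:
        inst.filters_applied.add("clumped")
    for chrom, start, end in _resolve_regions(cfg):
        inst = gwas_io.exclude_region(inst, chrom, start, end)
    if cfg.exclude_outcome_gws:
        inst = gwas_io.exclude_outcome_associated(inst, outcome, p_max=cfg.p_max)
    inst.excluded = len(inst) < cfg.min_snps
    return inst


def _battery(
    data: harmonize.HarmonizedDataset,
    exposure_id: str,
    cfg: RunConfig,
) -> tuple[list[dict], list[dict], list[dict], pd.DataFrame]:
    """Run the configured estimators + sensitivity analyses on one pair."""
    rows, loo_rows, presso_rows = [], [], []
    ivw_est = uvmr.ivw(data, model=cfg.ivw_model)
    if "ivw" in cfg.methods:
        rows.append({"exposure": exposure_id, **ivw_est.as_dict()})
    if "egger" in cfg.methods and data.n_snps >= 3:
        rows.append({"exposure": exposure_id, **uvmr.egger(data).as_dict()})
    if "wmedian" in cfg.methods and data.n_snps >= 3:
        est = uvmr.weighted_median(data, n_boot=cfg.wmedian_nboot, seed=cfg.seed)
        rows.append({"exposure": exposure_id, **est.as_dict()})
    for item in uvmr.leave_one_out(data, model=cfg.ivw_model):
        loo_rows.append(
            {
                "exposure": exposure_id,
                "dropped": item["dropped"],
                "beta": item["estimate"].beta,
                "se": item["estimate"].se,
                "pvalue": item["estimate"].pvalue,
                "flagged": item["flagged"],
            }
        )
    if cfg.presso and data.n_snps >= 4:
        try:
            res = _run_presso(data, n_sim=cfg.presso_nsim, seed=cfg.seed)
            presso_rows.append(
                {
                    "exposure": exposure_id,
                    "rss_observed": res.rss_observed,
                    "global_p": res.global_p,
                    "outliers": ",".join(res.outliers),
                    "corrected_beta": res.corrected_estimate.beta if res.corrected_estimate else float("nan"),
                    "corrected_p": res.corrected_estimate.pvalue if res.corrected_estimate else float("nan"),
                    "distortion_p": res.distortion_p if res.distortion_p is not None else float("nan"),
                    "note": "",
                }
            )
        except ValueError as err:
            logger.warning("%s: MR-PRESSO not reportable (%s)", exposure_id, err)
            presso_rows.append(
                {
                    "exposure": exposure_id,
                    "rss_observed": float("nan"),
                    "global_p": float("nan"),
                    "outliers": "",
                    "corrected_beta": float("nan"),
                    "corrected_p": float("nan"),
                    "distortion_p": float("nan"),
                    "note": str(err),
                }
            )
    funnel = uvmr.funnel_data(data)
    funnel.insert(0, "exposure", exposure_id)
    return rows, loo_rows, presso_rows, funnel


def _adjusted_alpha(cfg: RunConfig) -> tuple[float, float]:
    if cfg.corr_file is None:
        return cfg.alpha, float("nan")
    corr = multiple_testing.CorrelationMatrix.from_tsv(cfg.corr_file)
    meff = multiple_testing.effective_tests(corr)
    thr, _ = multiple_testing.adjusted_threshold(cfg.alpha, meff)
    return thr, meff


def _run_univariable(cfg: RunConfig, reverse: bool) -> dict:
    t0 = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = "reverse" if reverse else "forward"
    outcome = gwas_io.read_summary_stats(cfg.outcome_file, cfg.outcome_dialect)
    ld = None
    if cfg.ld_matrix_file:
        ld = pd.read_csv(cfg.ld_matrix_file, sep="\t", index_col=0)
    threshold, meff = _adjusted_alpha(cfg)

    rows, loo_rows, presso_rows, funnels = [], [], [], []
    audit: dict = {
        "config_hash": cfg.hash(),
        "seed": cfg.seed,
        "direction": tag,
        "threshold": threshold,
        "meff": meff,
        "exposures": {},
    }
    if reverse:
        # one instrument set (the disease GWAS), each metabolite in turn as outcome
        inst = _select_and_filter(
            outcome, _exposure_id(cfg.outcome_file), [], cfg, ld, do_clump=True
        )
        audit["exposures"][inst.exposure_id] = inst.audit()
        for path in cfg.exposure_files:
            met_id = _exposure_id(path)
            met = gwas_io.read_summary_stats(path, cfg.exposure_dialect)
            if inst.excluded:
                audit["exposures"][met_id] = {"excluded": True}
                continue
            data = harmonize.harmonize_pair(
                inst, met, palindrome_mode=cfg.palindrome_mode, maf_noninfer=cfg.maf_noninfer
            )
            r, l, pr, fu = _battery(data, f"{inst.exposure_id}->{met_id}", cfg)
            rows += r
            loo_rows += l
            presso_rows += pr
            funnels.append(fu)
            audit["exposures"][met_id] = data.report()
    else:
        for path in cfg.exposure_files:
            exp_id = _exposure_id(path)
            assocs = gwas_io.read_summary_stats(path, cfg.exposure_dialect)
            inst = _select_and_filter(assocs, exp_id, outcome, cfg, ld, do_clump=False)
            audit["exposures"][exp_id] = inst.audit()
            if inst.excluded:
                logger.warning("%s excluded at instrument selection; run continues", exp_id)
                continue
            data = harmonize.harmonize_pair(
                inst, outcome, palindrome_mode=cfg.palindrome_mode, maf_noninfer=cfg.maf_noninfer
            )
            audit["exposures"][exp_id]["harmonization"] = data.report()
            r, l, pr, fu = _battery(data, exp_id, cfg)
            rows += r
            loo_rows += l
            presso_rows += pr
            funnels.append(fu)

    results = pd.DataFrame(rows)
    if not results.empty:
        results["significant_adjusted"] = results["pvalue"] < threshold
    _write_tsv(results, out / f"results_{tag}.tsv", cfg)
    _write_tsv(pd.DataFrame(loo_rows), out / f"leave_one_out_{tag}.tsv", cfg)
    if presso_rows:
        _write_tsv(pd.DataFrame(presso_rows), out / f"presso_{tag}.tsv", cfg)
    if funnels:
        _write_tsv(pd.concat(funnels, ignore_index=True), out / f"funnel_{tag}.tsv", cfg)
    audit["runtime_s"] = round(time.time() - t0, 3)
    with open(out / f"audit_{tag}.json", "w") as fh:
        json.dump(audit, fh, indent=2, default=str)
    return {"results": results, "audit": audit}


def run_forward(cfg: RunConfig) -> dict:
    """Forward MR: each metabolite as exposure, the disease as outcome."""
    return _run_univariable(cfg, reverse=False)


def run_reverse(cfg: RunConfig) -> dict:
    """Reverse MR: the disease as exposure, each metabolite as outcome."""
    return _run_univariable(cfg, reverse=True)


def run_bma(cfg: RunConfig) -> dict:
    """Genetic-correlation pruning, multivariable harmonization, MR-BMA, diagnostics."""
    t0 = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outcome = gwas_io.read_summary_stats(cfg.outcome_file, cfg.outcome_dialect)
    proxies = None
    if cfg.proxy_file:
        pt = pd.read_csv(cfg.proxy_file, sep="\t")
        proxies = dict(zip(pt.iloc[:, 0].astype(str), pt.iloc[:, 1].astype(str)))

    instruments: dict[str, gwas_io.InstrumentSet] = {}
    priority: dict[str, float] = {}
    for path in cfg.exposure_files:
        exp_id = _exposure_id(path)
        assocs = gwas_io.read_summary_stats(path, cfg.exposure_dialect)
        inst = _select_and_filter(assocs, exp_id, outcome, cfg, None, do_clump=False)
        if inst.excluded:
            logger.warning("%s excluded at selection; not offered to BMA", exp_id)
            continue
        instruments[exp_id] = inst
        # priority for rg pruning: univariable IVW |z|
        data = harmonize.harmonize_pair(
            inst, outcome, palindrome_mode=cfg.palindrome_mode, maf_noninfer=cfg.maf_noninfer
        )
        est = uvmr.ivw(data, model=cfg.ivw_model)
        priority[exp_id] = abs(est.beta / est.se)

    kept = list(instruments)
    if cfg.rg_file:
        rg = mrbma.RgMatrix.from_tsv(cfg.rg_file)
        present = [e for e in rg.exposure_ids if e in instruments]
        idx = [rg.exposure_ids.index(e) for e in present]
        rg_sub = mrbma.RgMatrix(present, rg.rg[np.ix_(idx, idx)])
        kept = mrbma.prune_by_rg(rg_sub, priority, threshold=cfg.rg_threshold)

    data = harmonize.harmonize_multi(
        [instruments[e] for e in kept],
        outcome,
        proxy_table=proxies,
        palindrome_mode=cfg.palindrome_mode,
        maf_noninfer=cfg.maf_noninfer,
    )
    result = mrbma.bma(
        data,
        prior_p=cfg.bma_prior_p,
        sigma2=cfg.bma_sigma2,
        mode=cfg.bma_mode,
        z=cfg.bma_z,
        seed=cfg.seed,
    )
    _write_tsv(result.ranking(), out / "bma_mip_mace.tsv", cfg)
    _write_tsv(result.model_table(), out / "bma_models.tsv", cfg)

    diag_frames = []
    for subset, pp, _ in result.top_models(pp_min=0.1):
        d = mrbma.model_diagnostics(subset, data)
        frame = d.to_frame()
        frame.insert(0, "model", ",".join(subset))
        frame.insert(1, "pp", pp)
        diag_frames.append(frame)
    if diag_frames:
        _write_tsv(pd.concat(diag_frames, ignore_index=True), out / "bma_diagnostics.tsv", cfg)

    audit = {
        "config_hash": cfg.hash(),
        "seed": cfg.seed,
        "pruned_to": kept,
        "n_instruments": data.n_snps,
        "settings": result.settings,
        "runtime_s": round(time.time() - t0, 3),
    }
    with open(out / "audit_bma.json", "w") as fh:
        json.dump(audit, fh, indent=2, default=str)
    return {"bma": result, "data": data, "audit": audit}
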