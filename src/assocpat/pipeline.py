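"""End-to-end orchestration: data -> null model -> entropy -> dyads -> assortativity.

A :class:`PipelineConfig` describes either real input files (scan CSVs, an
attribute CSV, a supplant CSV) or a synthetic study (per-season generator
configs); :func:`run` executes the stages in order and writes every
artifact (entropy reports, the dyad table, the multimodel summary, a run
log) to the output directory, stamped with the config hash and seed.
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

from . import assortativity as asrt
from . import dyadic_association as dyad
from . import group_entropy as ent
from .null_model import bootstrap_scans, build_ensemble
from .scan_data import SeasonRoster, read_individuals, read_scans, summarize_dataset
from .synthetic import SyntheticConfig, generate_scan_dataset

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of one full analysis run."""

    outdir: str = "assocpat_out"
    seed: int = 0
    B: int = 1000                # permutations per season
    R: int = 1000                # bootstrap replicates per season
    n_selections: int = 1000     # dyad-flip selections
    alpha: float = 0.05
    engine: str = "fixed"
    refit_subsets: bool = True
    seasons: list = field(default_factory=list)      # season labels, in order
    # real-data inputs: {season: scan csv path}, plus attribute/supplant files
    scan_files: dict = field(default_factory=dict)
    attributes_file: str | None = None
    supplants_file: str | None = None
    start_years: dict = field(default_factory=dict)  # {season: calendar year of October start}
    # synthetic inputs: base generator settings applied to every season
    synthetic: dict | None = None

    def __post_init__(self):
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.seed is None:
            raise ValueError("seed must be set (no silent nondeterminism)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def hash(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("outdir", None)  # analytical identity is independent of where results land
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _load_or_generate(cfg: PipelineConfig):
    """Returns (datasets, rosters, ranks, ground_truths) keyed by season."""
    datasets, rosters, ranks, truths = {}, {}, {}, {}
    if cfg.synthetic is not None:
        seasons = cfg.seasons or ["2014/5", "2015/6", "2016/7"]
        base = dict(cfg.synthetic)
        roster_seed = int(base.pop("seed", cfg.seed))
        for i, season in enumerate(seasons):
            s_cfg = SyntheticConfig(
                **base, season=season, start_year=2014 + i, seed=(roster_seed + 7919 * i) % (2**31)
            )
            ds, gt = generate_scan_dataset(s_cfg)
            datasets[season], rosters[season], truths[season] = ds, ds.roster, gt
            ranks[season] = dict(zip(ds.ids, gt.rank.tolist()))
        return datasets, rosters, ranks, truths

    if not cfg.scan_files or cfg.attributes_file is None:
        raise FileNotFoundError("config must provide either synthetic settings or scan_files + attributes_file")
    individuals = read_individuals(cfg.attributes_file)
    daily = None
    if cfg.supplants_file:
        supplants = pd.read_csv(cfg.supplants_file)
        daily = asrt.daily_standardized_ranks(supplants)
    for season, path in cfg.scan_files.items():
        if not Path(path).exists():
            raise FileNotFoundError(f"scan file for season {season}: {path}")
        roster = SeasonRoster(season=season, members=individuals, start_year=cfg.start_years.get(season))
        ds = read_scans(path, roster)
        datasets[season], rosters[season] = ds, roster
        if daily is not None:
            ranks[season] = asrt.yearly_rank(daily)  # season split of supplants is the caller's concern
        else:
            ranks[season] = {i: 0.5 for i in ds.ids}
    return datasets, rosters, ranks, {}


def run(cfg: PipelineConfig) -> dict:
    """Execute the full analysis; returns the in-memory bundle.

    Stage order: scan data -> permutation ensembles -> entropy reports ->
    dyad tables (with bootstrap SDs) -> dyad-year rows -> multimodel
    inference with dyad-flip resampling for both response families.
    """
    t0 = time.time()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": cfg.hash(), "seed": cfg.seed}
    log_lines = [f"assocpat run {stamp['config_hash']} seed={cfg.seed}"]
    rng_seeds = np.random.SeedSequence(cfg.seed)

    def stage(name):
        log_lines.append(f"[{time.time() - t0:8.1f}s] {name}")
        log.info("stage: %s", name)

    try:
        stage("scan_data")
        datasets, rosters, ranks, truths = _load_or_generate(cfg)
        summaries = {s: summarize_dataset(d) for s, d in datasets.items()}

        entropy_reports = {}
        tables = {}
        seeds = rng_seeds.spawn(len(datasets))
        for child, (season, ds) in zip(seeds, sorted(datasets.items())):
            s_perm, s_boot = child.spawn(2)
            stage(f"null_model {season} (B={cfg.B})")
            ens = build_ensemble(ds, B=cfg.B, seed=s_perm)
            stage(f"group_entropy {season}")
            entropy_reports[season] = ent.entropy_report(ds, ens)
            stage(f"dyadic_association {season} (R={cfg.R})")
            boot = bootstrap_scans(ds, R=cfg.R, seed=s_boot)
            tables[season] = dyad.dyad_table(ds, ens, boot=boot, alpha=cfg.alpha)

        stage("assortativity: dyad rows")
        rows = asrt.build_dyad_rows(tables, rosters, ranks)
        stage(f"assortativity: dyad-flip multimodel inference (n_selections={cfg.n_selections})")
        flip_seed = int(rng_seeds.generate_state(1)[0] % (2**31))
        multimodel = {}
        for family in ("binomial", "gaussian"):
            multimodel[family] = asrt.dyad_flip_inference(
                rows,
                family=family,
                n_selections=cfg.n_selections,
                seed=flip_seed,
                engine=cfg.engine,
                refit_subsets=cfg.refit_subsets,
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline aborted in stage {log_lines[-1].split('] ')[-1]!r}: {exc}") from exc

    bundle = {
        "stamp": stamp,
        "summaries": summaries,
        "entropy": entropy_reports,
        "dyad_tables": tables,
        "dyad_rows": rows,
        "multimodel": multimodel,
        "truths": truths,
        "log": log_lines,
    }
    _write_bundle(bundle, out, cfg)
    return bundle


def _write_bundle(bundle: dict, out: Path, cfg: PipelineConfig) -> None:
    stamp = bundle["stamp"]
    with open(out / "entropy_report.json", "w") as fh:
        json.dump(
            {**stamp, "seasons": {s: r.to_dict() for s, r in bundle["entropy"].items()}},
            fh,
            indent=1,
        )
    table = pd.concat(bundle["dyad_tables"].values(), ignore_index=True)
    table.to_csv(out / "dyad_table.csv", index=False)
    bundle["dyad_rows"].to_csv(out / "dyad_rows.csv", index=False)

    mm_payload = {**stamp}
    for family, res in bundle["multimodel"].items():
        entry = {
            "n_selections": res.n_selections,
            "n_converged": res.n_converged,
            "mean_estimates": {k: float(v) for k, v in res.mean_estimates.items()},
        }
        if res.mean_summed_weights is not None:
            merged = res.mean_summed_weights.merge(res.predictor_expected, on="term")
            entry["predictors"] = merged.to_dict(orient="records")
        mm_payload[family] = entry
    with open(out / "multimodel_summary.json", "w") as fh:
        json.dump(mm_payload, fh, indent=1)

    with open(out / "summaries.json", "w") as fh:
        json.dump({**stamp, "seasons": bundle["summaries"]}, fh, indent=1)
    with open(out / "run.log", "w") as fh:
        fh.write("\n".join(bundle["log"]) + "\n")
    with open(out / "report.md", "w") as fh:
        fh.write(report(bundle))


def report(bundle: dict) -> str:
    """Human-readable markdown summary of a run bundle (deterministic)."""
    lines = ["# Association-pattern analysis", ""]
    lines.append(f"Config hash: `{bundle['stamp']['config_hash']}`, seed {bundle['stamp']['seed']}")
    lines.append("")
    lines.append("## Subgroup composition entropy")
    lines.append("")
    lines.append("| season | scans | H_obs (bits) | H_exp (bits) | ratio | unique |")
    lines.append("|---|---|---|---|---|---|")
    for season in sorted(bundle["entropy"]):
        r = bundle["entropy"][season]
        lines.append(
            f"| {season} | {r.n_scans} | {r.H_obs:.2f} | {r.H_exp:.2f} | {r.ratio:.4f} "
            f"| {r.unique_obs} ({100 * r.unique_frac:.0f}%) |"
        )
    lines.append("")
    lines.append("## Dyadic association")
    lines.append("")
    for season in sorted(bundle["dyad_tables"]):
        t = bundle["dyad_tables"][season]
        frac = t["significant"].mean()
        lines.append(
            f"- {season}: {len(t)} dyads, {t['significant'].sum()} significant associates "
            f"({100 * frac:.1f}%), max bootstrap SD {t['sri_sd_boot'].max():.4f}"
        )
    lines.append("")
    lines.append("## Predictors of preferred association")
    lines.append("")
    for family, res in bundle["multimodel"].items():
        lines.append(f"### {family}")
        lines.append("")
        if res.mean_summed_weights is not None:
            merged = res.mean_summed_weights.merge(res.predictor_expected, on="term")
            lines.append("| term | mean summed weight | expected weight |")
            lines.append("|---|---|---|")
            for _, row in merged.iterrows():
                lines.append(f"| {row['term']} | {row['mean_summed_weight']:.3f} | {row['expected_weight']:.3f} |")
        lines.append("")
        lines.append(f"Mean full-model estimates over {res.n_converged} converged selections:")
        lines.append("")
        for name, value in res.mean_estimates.items():
            lines.append(f"- `{name}`: {value:+.3f}")
        lines.append("")
    return "\n".join(lines) + "\n"
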