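"""End-to-end orchestration: screen -> index -> stratify -> DE -> clustering -> ORA.

:func:`run_pipeline` executes every stage on an expression matrix + survival
table, writing one TSV artifact per stage into the output directory as soon
as the stage finishes, and finally a JSON manifest with the config snapshot,
package version, per-stage row counts, the seed, timestamps and a SHA-256
hash of every artifact.  Numeric artifacts are deterministic given identical
inputs and seed.

Optional stages (over-representation without a GMT file; the shift test when
fewer than five DEGs exist) are logged and skipped; a failure in any required
stage aborts with the stage name and cause.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from . import diffexpr, enrich, structure
from .index import GeneSets, compute_index, evaluate_index, gene_sets_from_screen, stratify_index
from .io import align_samples, read_expression, read_survival
from .survival import screen_genes

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "PAPER_GENE_SETS"]

#: The published index gene sets: three harmful genes over one favorable gene.
PAPER_GENE_SETS = GeneSets(
    harmful=("LSM1", "LSM2", "LSM4"), favorable=("LSM8",)
)


@dataclass
class PipelineConfig:
    expression_path: str
    survival_path: str
    panel: Sequence[str]
    out_dir: str
    expression_format: str = "tsv"  # or geo_series_matrix
    alpha: float = 0.05
    harmful_override: Sequence[str] | None = None
    favorable_override: Sequence[str] | None = None
    cut_rule: str = "median"
    fc_cut: float = diffexpr.FC_CUT
    p_cut: float = diffexpr.P_CUT
    shift_method: str = "wilcoxon_signed"
    fuzzy_c: int = 2
    fuzzifier: float = 2.0
    gmt_path: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fc_cut <= 0 or not (0 < self.p_cut < 1):
            raise ValueError("fc_cut must be > 0 and p_cut in (0, 1)")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if not self.panel:
            raise ValueError("panel must be non-empty")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Parse a flat key=value config file (lists comma-separated)."""
        kv: dict[str, str] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value")
            k, v = line.split("=", 1)
            kv[k.strip()] = v.strip()
        known = set(cls.__dataclass_fields__)
        unknown = set(kv) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys: {sorted(unknown)}")

        def split(key: str) -> list[str] | None:
            return [g.strip() for g in kv[key].split(",")] if kv.get(key) else None

        kwargs: dict = {k: v for k, v in kv.items() if k in known}
        for key in ("panel", "harmful_override", "favorable_override"):
            if key in kwargs:
                kwargs[key] = split(key)
        for key, cast in (
            ("alpha", float), ("fc_cut", float), ("p_cut", float),
            ("fuzzifier", float), ("fuzzy_c", int), ("seed", int),
        ):
            if key in kwargs:
                kwargs[key] = cast(kwargs[key])
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return len(df)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written as manifest.json)."""
    t0 = _time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config": {k: (list(v) if isinstance(v, (list, tuple)) else v)
                   for k, v in asdict(cfg).items()},
        "started": _time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
        "artifacts": {},
    }

    def stage(name: str, rows: int, t_start: float) -> None:
        manifest["stages"][name] = {"rows": rows, "seconds": round(_time.time() - t_start, 3)}
        logger.info("stage %s: %d rows in %.2fs", name, rows, _time.time() - t_start)

    t = _time.time()
    expr = read_expression(cfg.expression_path, format=cfg.expression_format)
    surv = read_survival(cfg.survival_path)
    expr, surv = align_samples(expr, surv)
    stage("load", expr.shape[1], t)

    t = _time.time()
    screen = screen_genes(
        expr, surv, list(cfg.panel), alpha=cfg.alpha, cut_rule=cfg.cut_rule,
        include_harmful=cfg.harmful_override,
        include_favorable=cfg.favorable_override,
    )
    stage("screen", _write(screen, out / "screen.tsv"), t)

    t = _time.time()
    if cfg.harmful_override or cfg.favorable_override:
        gs = GeneSets(
            harmful=tuple(cfg.harmful_override or ()),
            favorable=tuple(cfg.favorable_override or ()),
        )
    else:
        gs = gene_sets_from_screen(screen)
    idx = compute_index(expr, gs)
    assign = stratify_index(idx, rule=cfg.cut_rule if cfg.cut_rule == "median" else "median")
    idx_out = assign.reset_index().rename(columns={"index": "sample_id"})
    stage("index", _write(idx_out, out / "index.tsv"), t)

    t = _time.time()
    ev = evaluate_index(assign, surv)
    ev_rows = pd.DataFrame(
        [
            dict(metric="logrank_chi2", value=ev.logrank_chi2),
            dict(metric="logrank_p", value=ev.logrank_p),
            dict(metric="group_hr", value=ev.cox_group.hr),
            dict(metric="group_ci_low", value=ev.cox_group.ci_low),
            dict(metric="group_ci_high", value=ev.cox_group.ci_high),
            dict(metric="group_p", value=ev.cox_group.p),
            dict(metric="continuous_hr_per_sd", value=ev.cox_continuous.hr),
            dict(metric="continuous_ci_low", value=ev.cox_continuous.ci_low),
            dict(metric="continuous_ci_high", value=ev.cox_continuous.ci_high),
            dict(metric="continuous_p", value=ev.cox_continuous.p),
        ]
    )
    stage("index_eval", _write(ev_rows, out / "index_eval.tsv"), t)

    t = _time.time()
    deg = diffexpr.group_compare(
        expr, assign["group"].to_numpy(), fc_cut=cfg.fc_cut, p_cut=cfg.p_cut
    )
    stage("deg", _write(deg, out / "deg.tsv"), t)

    t = _time.time()
    deg_sig = deg[deg["direction"].isin(["up", "down"])]
    if len(deg_sig) >= 5:
        shift = diffexpr.shift_test(deg_sig, method=cfg.shift_method)
        _write(
            pd.DataFrame([asdict(shift)]).rename(columns={"n": "n_genes"}),
            out / "shift.tsv",
        )
        stage("shift", _write(diffexpr.ecdf_points(deg_sig), out / "ecdf.tsv"), t)
    else:
        logger.info("shift stage skipped: only %d DEGs (< 5)", len(deg_sig))
        manifest["stages"]["shift"] = {"rows": 0, "skipped": "fewer than 5 DEGs"}

    t = _time.time()
    corr = structure.gene_correlation(expr, list(cfg.panel))
    stage("correlation", _write(corr.to_long(), out / "correlation.tsv"), t)

    t = _time.time()
    link = structure.cluster_genes_cosine(expr, list(cfg.panel))
    (out / "dendrogram.nwk").write_text(
        structure.dendrogram_to_newick(link, list(cfg.panel)) + "\n"
    )
    stage("dendrogram", len(cfg.panel), t)

    t = _time.time()
    part = structure.fuzzy_cluster_samples(
        expr, list(cfg.panel), c=cfg.fuzzy_c, fuzzifier=cfg.fuzzifier, seed=cfg.seed
    )
    mem = pd.DataFrame(
        part.membership,
        columns=[f"membership_{i + 1}" for i in range(part.membership.shape[1])],
    )
    mem.insert(0, "sample_id", part.sample_ids)
    mem["hard_label"] = part.hard_label
    stage("membership", _write(mem, out / "membership.tsv"), t)

    if cfg.gmt_path:
        t = _time.time()
        try:
            gsc = enrich.read_gmt(cfg.gmt_path)
            degs = deg_sig["gene"].tolist()
            enr = enrich.ora(degs, expr.gene_ids, gsc)
            stage("enrichment", _write(enr, out / "enrichment.tsv"), t)
        except ValueError as exc:
            logger.warning("enrichment stage skipped: %s", exc)
            manifest["stages"]["enrichment"] = {"rows": 0, "skipped": str(exc)}
    else:
        logger.info("enrichment stage skipped: no GMT collection supplied")
        manifest["stages"]["enrichment"] = {"rows": 0, "skipped": "no GMT supplied"}

    for p in sorted(out.iterdir()):
        if p.name != "manifest.json" and p.is_file():
            manifest["artifacts"][p.name] = _sha256(p)
    manifest["elapsed_seconds"] = round(_time.time() - t0, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
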