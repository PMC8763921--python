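"""End-to-end pipeline orchestration: prepare tables, run every workflow,
evaluate consensus and discrimination, and record a reproducible manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .discriminatory import auc_records, discrimination_summary
from .methods import METHOD_NAMES, MethodConfig, run_all
from .tables import (
    CountTable,
    GroupLabels,
    characterize,
    prevalence_filter,
    rarefy,
    read_count_table,
    read_metadata,
    write_count_table,
)
from .within_study import consensus_tally, jaccard_matrix, top_k_overlap

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "summarize"]


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    table_path: str
    metadata_path: str
    group_column: str
    out_dir: str
    taxonomy_path: str | None = None
    prevalence: float = 0.10
    rarefy_depth: str | int = "auto"
    methods: tuple[str, ...] = METHOD_NAMES
    alpha: float = 0.05
    seed: int = 42
    n_permutations: int = 999
    run_unfiltered: bool = True

    def validate(self) -> None:
        unknown = [m for m in self.methods if m not in METHOD_NAMES]
        if unknown:
            raise ValueError(f"unknown methods {unknown}; valid: {list(METHOD_NAMES)}")
        if not 0 <= self.prevalence <= 1:
            raise ValueError("prevalence must be in [0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _run_variant(
    name: str,
    table: CountTable,
    labels: GroupLabels,
    cfg: MethodConfig,
    config: RunConfig,
    out: Path,
) -> dict:
    variant_dir = out / name
    variant_dir.mkdir(parents=True, exist_ok=True)
    rarefied = rarefy(table, depth=config.rarefy_depth, seed=config.seed)
    write_count_table(table, variant_dir / "table.tsv")
    write_count_table(rarefied, variant_dir / "rarefied.tsv")
    labels_here = labels.restrict(table.sample_ids)
    results = run_all(table, rarefied, labels_here, cfg, methods=config.methods)
    files = {}
    for method, res in results.items():
        path = variant_dir / f"{method}.tsv"
        res.to_frame().to_csv(path, sep="\t", index=False)
        files[method] = str(path)
    tally = consensus_tally(results)
    pd.Series(tally.tally, name="n_methods").rename_axis("feature_id").to_csv(
        variant_dir / "consensus_tally.tsv", sep="\t"
    )
    if table.n_features >= 20:
        top = top_k_overlap(results, k=20)
        pd.Series(top.tally, name="n_methods").rename_axis("feature_id").to_csv(
            variant_dir / "top20_tally.tsv", sep="\t"
        )
    jac = jaccard_matrix(results)
    jac.to_csv(variant_dir / "jaccard.tsv", sep="\t")
    aucs = auc_records(table, labels_here)
    disc = discrimination_summary(results, aucs)
    disc_rows = []
    for method, summary in disc.items():
        row = {"method": method, "mean_auc": summary.mean_auc}
        for t, m in summary.metrics.items():
            for k, v in m.items():
                row[f"{k}_auc{t}"] = v
        disc_rows.append(row)
    pd.DataFrame(disc_rows).to_csv(variant_dir / "discrimination.tsv", sep="\t", index=False)
    chars = characterize(
        table, labels_here, n_permutations=config.n_permutations, seed=config.seed
    )
    (variant_dir / "characteristics.json").write_text(
        json.dumps(chars.as_dict(), indent=2)
    )
    artifacts = {
        str(p.relative_to(out)): _sha256(p) for p in sorted(variant_dir.glob("*"))
    }
    return {"result_files": files, "hashes": artifacts}


def run_pipeline(config: RunConfig) -> dict:
    """Run preparation, all requested workflows, and the evaluations.

    Produces, under ``out_dir``, an ``unfiltered/`` and a ``filtered/``
    variant (prevalence filter applied before re-rarefying), one result TSV
    per method, consensus/top-20/Jaccard/discrimination tables, dataset
    characteristics, and a JSON manifest with file hashes so identical
    config + seed yields identical hashes.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = read_count_table(config.table_path)
    labels = read_metadata(
        config.metadata_path, config.group_column, sample_ids=table.sample_ids
    )
    cfg = MethodConfig(alpha=config.alpha, seed=config.seed)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "alpha": config.alpha,
        "prevalence": config.prevalence,
        "rarefy_depth": config.rarefy_depth,
        "methods": list(config.methods),
        "stages": {},
    }
    variants: list[tuple[str, CountTable]] = []
    if config.run_unfiltered:
        variants.append(("unfiltered", table))
    variants.append(("filtered", prevalence_filter(table, config.prevalence)))
    for name, variant_table in variants:
        try:
            manifest["stages"][name] = {
                "status": "ok",
                **_run_variant(name, variant_table, labels, cfg, config, out),
            }
        except Exception as exc:  # noqa: BLE001 - manifest records the failure
            logger.exception("stage %s failed", name)
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    if any(s["status"] != "ok" for s in manifest["stages"].values()):
        raise RuntimeError(f"pipeline stage failed; see {manifest_path}")
    return manifest


def summarize(manifests: list[dict], variant: str = "filtered") -> dict[str, pd.DataFrame]:
    """Aggregate per-dataset pipeline outputs into cross-dataset tables.

    Returns the datasets x methods percent-significant matrix, the mean
    inter-tool Jaccard distance matrix, and the stacked characteristics.
    """
    if not manifests:
        raise ValueError("no manifests given")
    method_sets = [tuple(m["methods"]) for m in manifests]
    if len(set(method_sets)) != 1:
        raise ValueError(f"manifests disagree on methods: {sorted(set(method_sets))}")
    pct_rows = {}
    jaccards = []
    chars = {}
    for i, manifest in enumerate(manifests):
        stage = manifest["stages"][variant]
        files = stage["result_files"]
        name = f"dataset{i:03d}"
        row = {}
        for method, path in files.items():
            frame = pd.read_csv(path, sep="\t")
            row[method] = 100.0 * frame["significant"].sum() / len(frame)
        pct_rows[name] = row
        any_path = Path(next(iter(files.values())))
        jac_path = any_path.parent / "jaccard.tsv"
        jaccards.append(pd.read_csv(jac_path, sep="\t", index_col=0))
        chars_path = any_path.parent / "characteristics.json"
        chars[name] = json.loads(chars_path.read_text())
    pct = pd.DataFrame(pct_rows).T
    mean_jac = sum(j.to_numpy() for j in jaccards) / len(jaccards)
    mean_jac = pd.DataFrame(
        mean_jac, index=jaccards[0].index, columns=jaccards[0].columns
    )
    return {
        "pct_significant": pct,
        "mean_jaccard": mean_jac,
        "characteristics": pd.DataFrame(chars).T,
    }
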