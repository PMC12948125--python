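"""End-to-end pipeline: score -> map -> admixture -> correlation -> spots
-> sample topology, with a reproducibility manifest.

Every run writes plain-text artifacts (TSV, whitespace Q/P, JSON manifest)
plus PNG figures into a run directory.  All randomness is pinned by the
seeds recorded in the manifest, so re-running the same configuration
reproduces byte-identical TSV outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .admixture import align_components, cv_curve, fit_admixture, write_p_matrix
from .correlation import correlation_maps
from .genotype_io import (
    GenotypeMatrix,
    QMatrix,
    SampleGroups,
    polarize_to_minor,
    read_genotype_tsv,
    read_plink,
    read_q_matrix,
    write_q_matrix,
)
from .render import render_array, render_portrait
from .sample_topology import pairwise_correlation_map, silhouette, similarity_network
from .simulate import desk_profile, simulate_admixed
from .snp_score import compute_snp_score
from .som import (
    Portrait,
    SOMModel,
    mean_portrait,
    sample_portrait,
    save_model,
    supporting_maps,
    train_som,
)
from .spots import spot_correlation_network, spot_profiles, summary_maps

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "cmd_pipeline", "trait_overlay"]

STAGES = ("score", "som", "admixture", "correlation", "spots", "topology")


@dataclass
class RunConfig:
    """Pipeline configuration; round-trips losslessly through YAML."""

    # input: exactly one of genotype_tsv / plink_prefix / simulate_preset
    genotype_tsv: str | None = None
    plink_prefix: str | None = None
    simulate_preset: str | None = None
    q_files: dict[int, str] = field(default_factory=dict)  # ingest mode
    output_dir: str = "snpsom_run"
    width: int = 45
    height: int = 45
    epochs: int = 20
    k_list: list[int] = field(default_factory=lambda: [2, 3, 4, 5, 6])
    analysis_k: int | None = None  # default: last of k_list
    scc_threshold: float = 0.7
    spot_quantile: float = 0.98
    spot_min_units: int = 3
    cooccurrence_fraction: float = 0.5
    cv_folds: int = 0  # 0 disables the CV curve
    em_max_iter: int = 2000
    em_tol: float = 1e-4
    seed: int = 0
    component_nicknames: dict[str, str] = field(default_factory=dict)
    write_scores: bool = False
    render_png: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.scc_threshold <= 1.01:
            raise ValueError("scc_threshold out of range")
        if not 0 < self.spot_quantile <= 1:
            raise ValueError("spot_quantile out of range")
        if not 0 <= self.cooccurrence_fraction <= 1:
            raise ValueError("cooccurrence_fraction out of range")
        sources = [self.genotype_tsv, self.plink_prefix, self.simulate_preset]
        if sum(x is not None for x in sources) != 1:
            raise ValueError(
                "exactly one of genotype_tsv, plink_prefix, simulate_preset required"
            )

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["q_files"] = {int(k): v for k, v in (d.get("q_files") or {}).items()}
        return cls(**d)


def _tsv(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", **kw)


def _load_genotypes(cfg: RunConfig) -> GenotypeMatrix:
    if cfg.genotype_tsv:
        return read_genotype_tsv(cfg.genotype_tsv)
    if cfg.plink_prefix:
        return read_plink(Path(cfg.plink_prefix).with_suffix(".bed"))
    params = desk_profile(cfg.simulate_preset)
    geno, _ = simulate_admixed(seed=cfg.seed, **params)
    return geno


def cmd_pipeline(cfg: RunConfig) -> Path:
    """Run all stages; returns the run directory.

    Halts on the first failing stage (its name is in the raised error);
    artifacts of completed stages are retained.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": dataclasses.asdict(cfg),
        "stages_completed": [],
    }
    stage = "load"
    try:
        geno = polarize_to_minor(_load_genotypes(cfg))

        stage = "score"
        logger.info("stage score: G=%d S=%d", geno.n_snps, geno.n_samples)
        scores = compute_snp_score(geno)
        if cfg.write_scores:
            from .snp_score import write_score_tsv

            write_score_tsv(scores, out / "scores.tsv")
        manifest["stages_completed"].append(stage)

        stage = "som"
        logger.info(
            "stage som: grid %dx%d, epochs=%d, seed=%d",
            cfg.width, cfg.height, cfg.epochs, cfg.seed,
        )
        model = train_som(
            scores, width=cfg.width, height=cfg.height,
            epochs=cfg.epochs, seed=cfg.seed,
        )
        save_model(model, out / "som")
        maps = supporting_maps(model)
        rows, cols = np.divmod(np.arange(model.n_units), model.width)
        _tsv(
            pd.DataFrame(
                {
                    "unit": np.arange(model.n_units), "row": rows, "col": cols,
                    "variance": maps["variance_map"], "d": maps["d_map"],
                    "population": maps["population_map"],
                }
            ),
            out / "supporting_maps.tsv",
        )
        manifest["stages_completed"].append(stage)

        stage = "admixture"
        q_by_k: dict[int, QMatrix] = {}
        for k in cfg.k_list:
            if k in cfg.q_files:
                logger.info("stage admixture: ingesting K=%d from %s", k, cfg.q_files[k])
                q = read_q_matrix(cfg.q_files[k], geno.sample_ids)
            else:
                logger.info("stage admixture: fitting K=%d (seed=%d)", k, cfg.seed)
                q, p, trace = fit_admixture(
                    geno, k, seed=cfg.seed,
                    max_iter=cfg.em_max_iter, tol=cfg.em_tol,
                )
                write_p_matrix(p, out / f"admixture_K{k}.P")
                (out / f"admixture_K{k}.loglik.tsv").write_text(
                    "iter\tloglik\n"
                    + "".join(f"{i}\t{v:.6f}\n" for i, v in enumerate(trace))
                )
            q_by_k[k] = q
        # hierarchical alignment K -> K+1 for consistent component coloring
        ks = sorted(q_by_k)
        for a, b in zip(ks, ks[1:]):
            q_by_k[b], _ = align_components(q_by_k[a], q_by_k[b])
        for k, q in q_by_k.items():
            write_q_matrix(q, out / f"admixture_K{k}.Q")
        if cfg.cv_folds >= 2:
            curve = cv_curve(geno, cfg.k_list, n_folds=cfg.cv_folds, seed=cfg.seed)
            _tsv(curve.to_frame(), out / "cv_curve.tsv")
        manifest["stages_completed"].append(stage)

        k_use = cfg.analysis_k or cfg.k_list[-1]
        q_use = q_by_k[k_use]
        groups = SampleGroups.from_q(q_use, geno.sample_ids)

        stage = "correlation"
        logger.info("stage correlation: K=%d, threshold=%.2f", k_use, cfg.scc_threshold)
        cms = correlation_maps(model, q_use, threshold=cfg.scc_threshold)
        _tsv(cms.to_frame(), out / "correlation_maps.tsv")
        sel_rows = [
            {"component": comp, "snp_id": sid}
            for comp, snps in cms.selected_snps.items()
            for sid in snps
        ]
        _tsv(
            pd.DataFrame(sel_rows, columns=["component", "snp_id"]),
            out / "selected_snps.tsv",
        )
        if cfg.render_png:
            for i, comp in enumerate(cms.component_ids):
                render_array(
                    cms.maps[i].reshape(model.height, model.width), "correlation"
                ).save(out / f"correlation_map_{comp}.png")
        manifest["stages_completed"].append(stage)

        stage = "spots"
        logger.info("stage spots: quantile=%.3f", cfg.spot_quantile)
        portraits = [sample_portrait(model, sid) for sid in model.sample_ids]
        over, seg = summary_maps(
            portraits, quantile=cfg.spot_quantile,
            min_units=cfg.spot_min_units, model=model,
        )
        _tsv(
            pd.DataFrame(
                {"unit": np.arange(model.n_units), "row": rows, "col": cols,
                 "overexpression": over}
            ),
            out / "overexpression_map.tsv",
        )
        _tsv(seg.to_frame(), out / "spot_report.tsv")
        _tsv(
            pd.DataFrame(
                [
                    {"label": sp.label, "snp_id": sid}
                    for sp in seg.spots for sid in sp.snp_ids
                ],
                columns=["label", "snp_id"],
            ),
            out / "spot_snps.tsv",
        )
        if len(seg.spots) >= 2:
            profiles = spot_profiles(seg, model)
            profiles.index.name = "label"
            profiles.reset_index().to_csv(
                out / "spot_profiles.tsv", sep="\t", index=False,
                float_format="%.10g",
            )
            net = spot_correlation_network(profiles)
            _tsv(net.to_frame(), out / "spot_network.tsv")
        if cfg.render_png:
            for lab in groups.labels:
                name = cfg.component_nicknames.get(lab, lab)
                render_portrait(
                    mean_portrait(model, groups.members(lab), subject=name)
                ).save(out / f"mean_portrait_{name}.png")
            render_array(
                over.reshape(model.height, model.width), "standard"
            ).save(out / "overexpression_map.png")
        manifest["stages_completed"].append(stage)

        stage = "topology"
        logger.info("stage topology: %d samples, %d groups",
                    model.n_samples, len(groups.labels))
        pcm = pairwise_correlation_map(model, groups)
        pcm.to_frame().to_csv(
            out / "pcm.tsv", sep="\t", index_label="sample",
            float_format="%.10g",
        )
        sil = silhouette(pcm)
        _tsv(sil.table, out / "silhouette.tsv")
        coords, edges = similarity_network(pcm, seed=cfg.seed)
        _tsv(edges, out / "similarity_edges.tsv")
        _tsv(
            pd.DataFrame(
                [(s, x, y) for s, (x, y) in coords.items()],
                columns=["sample", "x", "y"],
            ),
            out / "similarity_layout.tsv",
        )
        if cfg.render_png:
            render_array(pcm.values, "correlation", pixel_scale=2).save(
                out / "pcm.png"
            )
        manifest["stages_completed"].append(stage)
    except Exception as exc:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def trait_overlay(
    traits: pd.Series,
    model: SOMModel,
    sample_order: list[str] | None = None,
    window: int = 20,
) -> tuple[dict[str, Portrait], pd.DataFrame]:
    """Per-category mean portraits plus sliding-window composition curves.

    ``traits`` is a categorical series indexed by sample id (missing
    samples allowed).  Along ``sample_order`` — typically samples sorted
    by admixture composition — the curve gives each category's running
    fraction over a window of ``window`` samples.
    """
    traits = traits.dropna()
    if traits.empty:
        raise ValueError("trait is missing for all samples")
    order = sample_order or [s for s in model.sample_ids if s in traits.index]
    order = [s for s in order if s in traits.index]
    if window > len(order):
        raise ValueError(
            f"window {window} longer than the {len(order)} samples with the trait"
        )
    cats = list(dict.fromkeys(traits.loc[order].tolist()))
    portraits = {
        cat: mean_portrait(
            model, [s for s in order if traits[s] == cat], subject=str(cat)
        )
        for cat in cats
    }
    onehot = pd.DataFrame(
        {cat: [1.0 if traits[s] == cat else 0.0 for s in order] for cat in cats},
        index=order,
    )
    curves = onehot.rolling(window=window, min_periods=window).mean().dropna()
    curves.index.name = "sample"
    return portraits, curves.reset_index()
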