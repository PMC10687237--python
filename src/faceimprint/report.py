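"""Orchestration and paper-style outputs.

Runs the full pipeline — simulate (or load), evaluate with grouped
repeated CV, BH selection, nested-input counts, occlusion maps, imprint
decomposition — and writes ranking tables, JSON summaries and figures to
an output directory.  Every output is reproducible from the serialized
config plus the global seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from ._utils import ConfigError, derive_seed
from . import synthetic
from .decompose import (
    DecompositionConfig,
    fit_decomposition,
    normalize_prototype,
    prominence_auc_correlation,
    prominence_scores,
)
from .evaluate import bh_select, count_significant, make_cv_plan, ranking_table, run_cv
from .features import EmbeddingInput, OvalSpec, make_backend
from .occlusion import occlusion_auc_map
from .predict import nested_input_runner

log = logging.getLogger("faceimprint")

__all__ = ["RunConfig", "run_megastudy", "render_reports", "group_mean_auc"]


@dataclass
class RunConfig:
    """End-to-end run settings (see example YAML in the README)."""

    outdir: str = "faceimprint_out"
    seed: int = 0
    dataset_path: str | None = None  # load instead of simulating
    synthetic: dict = field(default_factory=dict)  # SyntheticConfig overrides
    backend: str = "pixel_pca"
    d_embed: int = 100
    d_reduce: int | None = None
    n_repeats: int = 20
    n_folds: int = 5
    q: float = 0.05
    nested: bool = True
    occlusion_variables: list = field(default_factory=list)
    occlusion_grid: int = 8
    occlusion_fill: str = "train_mean"
    decompose: bool = True
    lambda_: float = 0.01
    symmetry: bool = True
    solver: str = "owlqn"
    max_iter: int = 2000
    group_mapping: str | None = None  # CSV variable,group

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.n_folds < 2 or self.n_repeats < 1:
            raise ConfigError("need n_folds >= 2 and n_repeats >= 1")
        if not (0 < self.q < 1):
            raise ConfigError("q must be in (0,1)")
        # fail fast on sub-configs before any compute
        self.synthetic_config()
        DecompositionConfig(
            lambda_=self.lambda_, symmetry=self.symmetry, solver=self.solver,
            max_iter=self.max_iter,
        )

    def synthetic_config(self) -> synthetic.SyntheticConfig:
        kwargs = dict(self.synthetic)
        kwargs.setdefault("seed", derive_seed(self.seed, "synthetic"))
        return synthetic.SyntheticConfig(**kwargs)


def _load_or_simulate(config: RunConfig):
    if config.dataset_path:
        images, attrs, manifest = synthetic.read_dataset(config.dataset_path)
        if manifest.get("oval") is None:
            raise ConfigError("dataset manifest lacks a face-oval specification")
        oval = OvalSpec.from_geometry(manifest["oval"])
        return images, attrs, oval
    sc = config.synthetic_config()
    images, attrs, _ = synthetic.make_dataset(sc)
    oval = OvalSpec.from_geometry(synthetic.face_oval_geometry(sc.image_size))
    return images, attrs, oval


def run_megastudy(config: RunConfig) -> dict:
    """Execute the configured pipeline; returns paths of written outputs."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(dataclasses.asdict(config)))
    logging.basicConfig(level=logging.INFO)
    written = {"config": out / "config.yaml"}

    log.info("stage=data start")
    images, attrs, oval = _load_or_simulate(config)
    log.info("stage=data end n_images=%d m=%d", images.n, attrs.m)

    plan = make_cv_plan(
        attrs, n_repeats=config.n_repeats, n_folds=config.n_folds,
        seed=derive_seed(config.seed, "cv"),
    )

    log.info("stage=evaluate start (embedding input)")
    embed = EmbeddingInput(
        make_backend(config.backend, d=config.d_embed,
                     seed=derive_seed(config.seed, "backend")),
        d_reduce=config.d_reduce,
    )
    targets = [n for n, d in zip(attrs.names, attrs.demographic) if not d] or list(
        attrs.names
    )
    results = run_cv(images, attrs, plan, embed, targets=targets, q=config.q)
    for r in results.values():
        if r.k < plan.n_repeats * plan.n_folds:
            log.info("variable=%s k=%d (skipped folds)", r.name, r.k)
    table = ranking_table(results)
    table.to_csv(out / "ranking.csv", index=False, float_format="%.10g")
    written["ranking"] = out / "ranking.csv"

    bh = bh_select([r.p_value for r in results.values()], q=config.q,
                   names=list(results))
    summary = {
        "n_variables": len(results),
        "bh_q": config.q,
        "bh_cutoff": bh.cutoff,
        "n_bh_significant": bh.n_rejected,
        "expected_false_positives": bh.expected_false_positives,
        "n_two_se_significant": int(
            sum(bool(r.two_se_significant) for r in results.values())
        ),
    }
    log.info("stage=evaluate end %s", summary)

    if config.nested and attrs.demographic.any():
        log.info("stage=nested start")
        nested = nested_input_runner(
            images, attrs, oval, plan=plan, backend=config.backend,
            d_embed=config.d_embed, d_reduce=config.d_reduce,
            seed=derive_seed(config.seed, "backend"), q=config.q,
        )
        counts = count_significant(nested, q=config.q)
        counts.to_csv(out / "nested_counts.csv", index=False, float_format="%.10g")
        written["nested_counts"] = out / "nested_counts.csv"
        log.info("stage=nested end\n%s", counts)

    for var in config.occlusion_variables:
        log.info("stage=occlusion start variable=%s", var)
        omap = occlusion_auc_map(
            images, attrs, var, plan, embed,
            grid_size=config.occlusion_grid, fill_policy=config.occlusion_fill,
        )
        pd.DataFrame(omap.decrease).to_csv(
            out / f"occlusion_{var}.csv", index=False, float_format="%.10g"
        )
        fig = heatmap_overlay(omap, images.pixels[0])
        fig.savefig(out / f"occlusion_{var}.png", dpi=120)
        plt.close(fig)
        written[f"occlusion_{var}"] = out / f"occlusion_{var}.csv"

    if config.decompose:
        log.info("stage=decompose start")
        dconf = DecompositionConfig(
            lambda_=config.lambda_, symmetry=config.symmetry,
            solver=config.solver, max_iter=config.max_iter,
        )
        fit = fit_decomposition(images, attrs, dconf)
        v = prominence_scores(fit.prototypes)
        prom = pd.DataFrame({"variable": attrs.names, "prominence": v})
        prom.to_csv(out / "prominence.csv", index=False, float_format="%.10g")
        written["prominence"] = out / "prominence.csv"
        gallery_dir = out / "prototypes"
        gallery_dir.mkdir(exist_ok=True)
        _write_prototype_pngs(fit.prototypes, attrs.names, gallery_dir)
        auc_by_var = {r.name: r.mean for r in results.values() if r.mean is not None}
        common = [n for n in attrs.names if n in auc_by_var]
        if len(common) >= 3:
            idx = [attrs.names.index(n) for n in common]
            corr = prominence_auc_correlation(
                v[idx], [auc_by_var[n] for n in common]
            )
            if corr is not None:
                summary["prominence_auc_pearson_r"] = corr[0]
                summary["prominence_auc_r2"] = corr[1]
        summary["decomposition_final_loss"] = fit.final_loss
        summary["decomposition_iterations"] = fit.n_iter
        log.info("stage=decompose end iterations=%d", fit.n_iter)

    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    written["summary"] = out / "summary.json"
    render_reports(results, out, group_mapping=config.group_mapping)
    return written


def _write_prototype_pngs(protos, names, outdir: Path) -> None:
    """One PNG per imprint, mid-gray = 0, scaled by max |P_j|."""
    import imageio.v3 as iio
    import warnings

    for j, name in enumerate(names):
        Pj = protos.P[j + 1]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            norm = normalize_prototype(Pj)
        arr = np.round((norm + 1.0) / 2.0 * 255).astype(np.uint8)
        iio.imwrite(outdir / f"{name}.png", arr)


def group_mean_auc(results: dict, mapping: pd.DataFrame) -> pd.DataFrame:
    """Group mean AUC: average of cross-validated AUC means over the
    variables mapped to each group."""
    if not {"variable", "group"} <= set(mapping.columns):
        raise ConfigError("group mapping needs 'variable' and 'group' columns")
    rows = []
    for group, sub in mapping.groupby("group"):
        means = [
            results[v].mean
            for v in sub["variable"]
            if v in results and results[v].mean is not None
        ]
        if means:
            rows.append({"group": group, "mean_auc": float(np.mean(means)),
                         "n_variables": len(means)})
    return pd.DataFrame(rows).sort_values("mean_auc", ignore_index=True)


def forest_plot(results: dict, top: int = 40):
    """AUC means with 2SE intervals, sorted by increasing p-value."""
    table = ranking_table(results).head(top).iloc[::-1]
    fig, ax = plt.subplots(figsize=(6, max(3, 0.22 * len(table))))
    ypos = np.arange(len(table))
    ax.errorbar(table["mean_auc"], ypos, xerr=2 * table["se"], fmt="o",
                ms=3, capsize=2)
    ax.axvline(0.5, color="gray", ls="--", lw=1)
    ax.set_yticks(ypos)
    ax.set_yticklabels(table["variable"], fontsize=6)
    ax.set_xlabel("hold-out AUC (mean ± 2SE)")
    fig.tight_layout()
    return fig


def heatmap_overlay(omap, background: np.ndarray):
    """Occlusion heat map over a representative image; color scale peaks at
    the maximum cell decrease."""
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(background, cmap="gray", vmin=0, vmax=1)
    up = np.kron(omap.decrease, np.ones(
        (background.shape[0] // omap.grid_size,
         background.shape[1] // omap.grid_size)
    ))
    vmax = float(np.abs(omap.decrease).max()) or 1.0
    im = ax.imshow(up, cmap="hot", alpha=0.5, vmin=0, vmax=vmax)
    fig.colorbar(im, ax=ax, label="AUC decrease")
    ax.set_title(omap.variable, fontsize=9)
    ax.axis("off")
    return fig


def render_reports(results: dict, outdir, group_mapping=None) -> list[Path]:
    """Forest chart and (if a variable->group mapping CSV is supplied) a
    group-mean AUC chart."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    fig = forest_plot(results)
    p = outdir / "auc_forest.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    paths.append(p)
    if group_mapping is not None:
        try:
            mapping = pd.read_csv(group_mapping)
        except FileNotFoundError:
            log.warning("group mapping %s not found; skipping group chart",
                        group_mapping)
            return paths
        gm = group_mean_auc(results, mapping)
        fig, ax = plt.subplots(figsize=(5, max(2, 0.3 * len(gm))))
        ax.barh(gm["group"], gm["mean_auc"])
        ax.axvline(0.5, color="gray", ls="--", lw=1)
        ax.set_xlabel("group mean AUC")
        fig.tight_layout()
        p = outdir / "group_mean_auc.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)
    return paths
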