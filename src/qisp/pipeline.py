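"""End-to-end orchestration: screen -> extract -> validate -> cluster -> summarize.

The pipeline mirrors the study design it models: a fold-change screen of a
sorted-population expression matrix selects up-regulated candidates; each
candidate's ISH image is densitometered into a QISP; VZ-dominant profiles are
removed by the deep-ratio criterion; the surviving profiles are clustered on
correlation distance and grouped into deep / middle / upper laminar zones.

A JSON manifest records parameters, seeds and per-stage counts, satisfying
the conservation identities::

    screened-up = imaged + missing-image
    imaged      = valid + invalid
    valid       = sum of zone counts
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import ZoneMap, cluster_qisps, group_summary
from .extraction import RoiSpec, extract_qisp
from .io import read_image, write_image, write_json, write_qisp_table
from .screen import ExpressionMatrix, derive_threshold, screen_genes
from .synthetic import (
    RenderParams,
    generate_expression_matrix,
    generate_truth_profiles,
    render_ish_image,
)
from .validation import reports_to_frame, validate_qisps

__all__ = ["PipelineConfig", "run_pipeline", "make_demo_dataset"]


@dataclass
class PipelineConfig:
    """Everything one run needs; round-trips through YAML unchanged."""

    expression_tsv: str
    groups_tsv: str
    images_dir: str
    rois_dir: str
    output_dir: str
    controls_txt: str | None = None
    threshold: float | None = None  # overrides control-derived threshold
    fold_cutoff: float = 3.0
    target_group: str = "GFP+"
    reference_group: str = "GFP-"
    density_mode: str = "linear"
    validation_variant: str = "smoothed"
    linkage: str = "average"
    k: int = 3
    zone_deep_end: int = 10  # last deep bin
    zone_middle_end: int = 15  # last middle bin
    missing_image_policy: str = "skip"  # or "fail"
    annotations_tsv: str | None = None
    seed: int = 0

    def zone_map(self) -> ZoneMap:
        return ZoneMap(
            deep_bins=tuple(range(1, self.zone_deep_end + 1)),
            middle_bins=tuple(range(self.zone_deep_end + 1, self.zone_middle_end + 1)),
            upper_bins=tuple(range(self.zone_middle_end + 1, 21)),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; write per-stage outputs and return the manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    for attr in ("expression_tsv", "groups_tsv", "images_dir", "rois_dir"):
        p = Path(getattr(config, attr))
        if not p.exists():
            raise FileNotFoundError(f"{attr} does not exist: {p}")
    if config.missing_image_policy not in ("skip", "fail"):
        raise ValueError("missing_image_policy must be 'skip' or 'fail'")

    # --- stage 1: expression screen -------------------------------------
    matrix = ExpressionMatrix.from_tsv(config.expression_tsv, config.groups_tsv)
    if config.threshold is not None:
        threshold = float(config.threshold)
    else:
        if config.controls_txt is None:
            raise ValueError("provide either a threshold or a control gene list")
        controls = [
            line.strip()
            for line in Path(config.controls_txt).read_text().splitlines()
            if line.strip()
        ]
        control_vals = matrix.values.loc[controls].to_numpy().ravel()
        threshold = derive_threshold(control_vals)
    screen = screen_genes(
        matrix,
        config.target_group,
        config.reference_group,
        threshold,
        config.fold_cutoff,
    )
    screen.to_tsv(out / "screen.tsv")
    write_json(screen.summary(), out / "screen_summary.json")

    # --- stage 2: QISP extraction for up-regulated genes -----------------
    images_dir, rois_dir = Path(config.images_dir), Path(config.rois_dir)
    qisps, missing = [], []
    for gene in screen.up_genes:
        image_path = None
        for ext in (".png", ".tif", ".tiff"):
            cand = images_dir / f"{gene}{ext}"
            if cand.exists():
                image_path = cand
                break
        roi_path = rois_dir / f"{gene}.json"
        if image_path is None or not roi_path.exists():
            if config.missing_image_policy == "fail":
                raise FileNotFoundError(f"no image/ROI for screened gene {gene!r}")
            missing.append(gene)
            continue
        image = read_image(image_path)
        roi = RoiSpec.from_json(roi_path)
        qisps.append(
            extract_qisp(
                image, roi, gene, mode=config.density_mode, image_id=image_path.name
            )
        )
    write_qisp_table(qisps, out / "qisps.tsv")

    # --- stage 3: deep-ratio validation ----------------------------------
    reports, retained = validate_qisps(qisps, variant=config.validation_variant)
    reports_to_frame(reports).to_csv(
        out / "validation.tsv", sep="\t", index=False, float_format="%.6g"
    )

    # --- stage 4: clustering and zone grouping ---------------------------
    profiles = {
        q.gene_id: q.profile(config.validation_variant) for q in retained
    }
    summary_df = None
    if len(profiles) >= 2:
        k = min(config.k, len(profiles))
        result = cluster_qisps(
            profiles, k=k, linkage=config.linkage, zones=config.zone_map()
        )
        result.labels_frame().to_csv(out / "clusters.tsv", sep="\t", index=False)
        (out / "tree.nwk").write_text(result.tree.to_newick() + "\n")
        cent = pd.DataFrame(
            {cid: c for cid, c in result.centroids.items()}
        ).T
        cent.columns = [f"sroi_{i}" for i in range(1, 21)]
        cent.index.name = "cluster"
        cent.to_csv(out / "centroids.tsv", sep="\t", float_format="%.6g")
        summary_df = group_summary(result.zone_of_gene)
        summary_df.to_csv(out / "zone_summary.tsv", sep="\t", index=False)
        zone_counts = dict(zip(summary_df["zone"], summary_df["count"]))
    else:
        zone_counts = {}

    # --- manifest ---------------------------------------------------------
    manifest = {
        "qisp_version": __version__,
        "config": asdict(config),
        "threshold": threshold,
        "counts": {
            "genes_total": len(matrix.gene_ids),
            "eligible": int(len(screen.fold_of)),
            "up": len(screen.up_genes),
            "down": len(screen.down_genes),
            "imaged": len(qisps),
            "missing_image": len(missing),
            "valid": len(retained),
            "invalid": len(qisps) - len(retained),
            "clustered": len(profiles) if len(profiles) >= 2 else 0,
            "zones": {z: int(c) for z, c in zone_counts.items()},
        },
        "missing_genes": missing,
    }
    write_json(manifest, out / "manifest.json")
    return manifest


def make_demo_dataset(
    outdir: str | Path,
    seed: int = 0,
    n_genes: int = 60,
    deep_invalid_frac: float = 0.0,
    noise_sd: float = 0.01,
    replicate_sd: float = 0.25,
) -> PipelineConfig:
    """Write a complete miniature study to ``outdir`` and return its config.

    Produces an expression table with planted >= 3-fold up-regulation, a
    negative-control list, one rendered ISH image + ROI per gene, an
    annotation table, the truth bundle, and a ready-to-run ``config.yaml``.
    The default 60-gene set splits evenly over VZ / IZ / CP single-peak
    archetypes; ``deep_invalid_frac`` diverts that fraction to the invalid
    deep-biased archetype.
    """
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    (outdir / "rois").mkdir(parents=True, exist_ok=True)

    rest = 1.0 - deep_invalid_frac
    mix = {
        "vz_peak": rest / 3,
        "iz_peak": rest / 3,
        "cp_peak": rest / 3,
    }
    if deep_invalid_frac > 0:
        mix["deep_invalid"] = deep_invalid_frac

    truth_ss, expr_ss, render_ss = np.random.SeedSequence(seed).spawn(3)
    truth_seed = int(truth_ss.generate_state(1)[0] % (2**31))
    expr_seed = int(expr_ss.generate_state(1)[0] % (2**31))
    truth = generate_truth_profiles(n_genes, mix, seed=truth_seed)
    truth.write(outdir / "truth.tsv")

    matrix, controls = generate_expression_matrix(
        truth, replicate_sd=replicate_sd, seed=expr_seed
    )
    matrix.to_tsv(outdir / "expression.tsv", outdir / "groups.tsv")
    (outdir / "controls.txt").write_text("\n".join(controls) + "\n")

    render = RenderParams(noise_sd=noise_sd)
    image_seeds = render_ss.spawn(len(truth.gene_ids))
    for g, ss in zip(truth.gene_ids, image_seeds):
        img_seed = int(ss.generate_state(1)[0] % (2**31))
        image, roi = render_ish_image(truth.true_profiles[g], render, seed=img_seed)
        write_image(outdir / "images" / f"{g}.png", image)
        roi.to_json(outdir / "rois" / f"{g}.json")

    # toy annotation table: archetype-themed terms
    terms = {
        "vz_peak": "ventricular zone; progenitor",
        "iz_peak": "intermediate zone; migration",
        "cp_peak": "cortical plate; differentiation",
        "deep_invalid": "ventricular zone; apical",
        "flat": "housekeeping",
    }
    ann_rows = []
    for g in truth.gene_ids:
        for t in terms[truth.archetype_of[g]].split("; "):
            ann_rows.append({"gene_id": g, "term": t})
    pd.DataFrame(ann_rows).to_csv(outdir / "annotations.tsv", sep="\t", index=False)

    config = PipelineConfig(
        expression_tsv=str(outdir / "expression.tsv"),
        groups_tsv=str(outdir / "groups.tsv"),
        images_dir=str(outdir / "images"),
        rois_dir=str(outdir / "rois"),
        output_dir=str(outdir / "results"),
        controls_txt=str(outdir / "controls.txt"),
        annotations_tsv=str(outdir / "annotations.tsv"),
        seed=seed,
    )
    config.to_yaml(outdir / "config.yaml")
    return config
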