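"""End-to-end orchestration: image -> features -> diagnosis.

Stages: channel fusion -> segmentation -> skeleton graph -> radius profile ->
3D surface -> reduced-order hemodynamics -> feature table -> feature
selection + leave-one-out classification.  Every stage writes its artifact
under the output directory and the manifest records a hash for each file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from fvs3d import channels as ch
from fvs3d import hemodynamics as hemo
from fvs3d import profiling as prof
from fvs3d import segmentation as seg
from fvs3d import selection as sel
from fvs3d import skeleton as sk
from fvs3d import surface as surf
from fvs3d import synthetic as synth

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    seed: int = 0
    px_size: float | None = None        # cm per pixel; must be set explicitly
    roi: tuple[int, int, int, int] | None = None
    synthetic: dict = field(default_factory=lambda: dict(
        n_subjects=20, narrowed_fraction=0.5, narrowing=0.7,
        image_size=(256, 256), n_branch_levels=3, root_radius=8.0,
        radius_decay=0.8))
    fusion: dict = field(default_factory=lambda: dict(g=1.0))
    segmentation: dict = field(default_factory=lambda: dict(
        method="vesselness", low=0.20, high=0.40))
    profile: dict = field(default_factory=lambda: dict(
        canny_sigma=None, canny_low=0.1, canny_high=0.2,
        interval=None, max_search=25.0, edge_source="mask"))
    model: dict = field(default_factory=lambda: dict(
        n_pts=24, radius_ratio_threshold=1.5,
        smooth_iterations=3, smooth_lambda=0.5))
    simulate: dict = field(default_factory=lambda: dict(
        mu=0.035, T=32, period=1.0, peak_flow=0.01))
    classify: dict = field(default_factory=lambda: dict(
        method="ftest_scan", classifier="svm"))

    def validate(self) -> None:
        if self.px_size is None or self.px_size <= 0:
            raise ValueError("px_size (cm per pixel) must be set and positive")

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text) or {}
        cfg = cls(**{k: v for k, v in d.items()
                     if k in {f.name for f in dataclasses.fields(cls)}})
        if cfg.roi is not None:
            cfg.roi = tuple(cfg.roi)
        if "image_size" in cfg.synthetic:
            cfg.synthetic["image_size"] = tuple(cfg.synthetic["image_size"])
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def segment_image(image: np.ndarray, cfg: PipelineConfig,
                  model: "seg.DenseBlockUnet | None" = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Fused grayscale -> probability map -> binary mask."""
    gray = ch.fuse_channels(image, ch.ChannelProportion.from_g(cfg.fusion["g"]))
    scfg = cfg.segmentation
    if model is not None or scfg.get("method") == "denseblock_unet":
        if model is None:
            raise ValueError("denseblock_unet method needs a trained model")
        prob = seg.predict_prob_map(model, gray)
        mask = prob >= scfg.get("threshold", 0.5)
    else:
        prob = seg.vesselness_segmenter(gray)
        mask = seg.hysteresis_mask(prob, scfg.get("low", 0.08),
                                   scfg.get("high", 0.20))
    if scfg.get("largest_component", True):
        mask = _largest_component(mask)
    return prob, mask


def _largest_component(mask: np.ndarray) -> np.ndarray:
    """Keep the largest 8-connected foreground component (drops noise blobs
    and vessel fragments that cannot join the flow network)."""
    from scipy import ndimage

    lab, n = ndimage.label(mask, structure=np.ones((3, 3), int))
    if n <= 1:
        return mask
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    return lab == (1 + int(np.argmax(sizes)))


def subject_pipeline(image: np.ndarray, cfg: PipelineConfig,
                     model=None) -> dict:
    """Run one image through every geometric/hemodynamic stage.

    Returns a dict with the intermediates: prob, mask, graph, profile, mesh,
    solution, features (pandas Series).
    """
    cfg.validate()
    prob, mask = segment_image(image, cfg, model)
    graph = sk.skeleton_to_graph(mask, roi=cfg.roi)
    pcfg = cfg.profile
    if pcfg.get("edge_source", "mask") == "mask":
        edges = prof.edges_from_mask(mask, pcfg["canny_low"], pcfg["canny_high"])
    else:
        gray = ch.fuse_channels(image, ch.ChannelProportion.from_g(cfg.fusion["g"]))
        edges = prof.detect_edges(gray, pcfg["canny_low"], pcfg["canny_high"],
                                  pcfg.get("canny_sigma") or 1.0)
    profile = prof.profile_graph(graph, edges, interval=pcfg.get("interval"),
                                 max_search=pcfg.get("max_search", 25.0),
                                 px_size=cfg.px_size)
    mcfg = cfg.model
    mesh = surf.build_surface(profile, n_pts=mcfg["n_pts"],
                              radius_ratio_threshold=mcfg["radius_ratio_threshold"],
                              smooth_iterations=mcfg["smooth_iterations"],
                              smooth_lambda=mcfg["smooth_lambda"])
    scfg = cfg.simulate
    sol, features = hemo.simulate_tree(profile, mu=scfg["mu"],
                                       T=scfg["T"], period=scfg["period"],
                                       peak_flow=scfg["peak_flow"])
    return dict(prob=prob, mask=mask, graph=graph, profile=profile,
                mesh=mesh, solution=sol, features=features)


def _subject_with_retry(image, cfg: PipelineConfig, model=None):
    """A subject whose mask yields a degenerate vessel graph is retried with
    progressively more permissive hysteresis thresholds before giving up."""
    import copy

    last: Exception | None = None
    for low, high in [(None, None), (0.15, 0.30), (0.10, 0.25)]:
        c = cfg if low is None else copy.deepcopy(cfg)
        if low is not None:
            c.segmentation.update(low=low, high=high)
        try:
            return subject_pipeline(image, c, model)
        except (ValueError, RuntimeError) as exc:
            last = exc
    raise last


def cohort_feature_table(bundles, cfg: PipelineConfig,
                         model=None) -> sel.FeatureTable:
    """Per-subject features aligned into one table.

    Subjects whose extracted trees expose different numbers of faces yield
    differing feature names; only the columns present for every subject are
    kept (the derived Qmax/Step features always exist).
    """
    rows, labels, names = [], [], []
    for i, b in enumerate(bundles):
        res = _subject_with_retry(b.image, cfg, model)
        rows.append(res["features"])
        labels.append(b.tree.class_label)
        names.append(f"s{i:03d}")
    df = pd.DataFrame(rows, index=names)
    df = df.dropna(axis=1)
    return sel.FeatureTable(features=df,
                            labels=pd.Series(labels, index=names))


def classify_cohort(table: sel.FeatureTable, cfg: PipelineConfig) -> dict:
    ccfg = cfg.classify
    method = ccfg.get("method", "ftest_scan")
    seed = cfg.seed
    from sklearn.svm import SVC

    clf = SVC(random_state=seed)
    if method == "ftest_scan":
        result = sel.ftest_threshold_scan(table, classifier=clf, seed=seed)
    elif method == "ttest":
        result = sel.ttest_filter(table, alpha=ccfg.get("alpha", 0.05))
    elif method == "best_first":
        result = sel.best_first_search(table, classifier=clf, seed=seed)
    else:
        raise ValueError(f"unknown selection method: {method}")
    accuracies = sel.evaluate_classifiers(table, result, seed=seed)
    return dict(selection=result, accuracies=accuracies)


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path,
                 bundles=None) -> Path:
    """Full cohort run; writes intermediates and a hash manifest.

    Without ``bundles`` a synthetic cohort is generated from
    ``cfg.synthetic`` and ``cfg.seed``.
    """
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": {}, "files": {}}
    (out / "config.yaml").write_text(cfg.to_yaml())

    if bundles is None:
        scfg = dict(cfg.synthetic)
        bundles = synth.make_cohort(seed=cfg.seed, **scfg)
    manifest["stages"]["synth"] = {"n_subjects": len(bundles)}

    table = cohort_feature_table(bundles, cfg)
    table.to_csv(out / "features.csv", out / "labels.csv")
    manifest["stages"]["features"] = {
        "n_subjects": table.n_subjects,
        "n_features": table.features.shape[1]}

    result = classify_cohort(table, cfg)
    report = {
        "method": result["selection"].method,
        "selected": result["selection"].selected,
        "accuracies": result["accuracies"],
        "details": {k: v for k, v in result["selection"].details.items()
                    if k != "trace"},
    }
    (out / "classification.json").write_text(json.dumps(report, indent=2))
    manifest["stages"]["classify"] = {
        "n_selected": len(result["selection"].selected)}

    for f in sorted(out.glob("*")):
        if f.name != "manifest.json" and f.is_file():
            manifest["files"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
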