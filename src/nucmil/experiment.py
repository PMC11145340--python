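"""End-to-end pipeline on synthetic slides.

Wires every stage together: generate seeded slides, assemble each into
an image, extract tissue and cut 512-px tiles, compute patch features
with the pluggable extractor, build per-tile nucleus graphs from the
instance masks and handcrafted features, train the constrained MIL
model on the 7:1:2 split, and report test metrics.
"""

from __future__ import annotations

import json
from dataclasses import asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, feature_table
from .graph import NucleiGraph, build_knn_graph
from .metrics import MetricReport, confusion, metrics
from .mil import PatchBag
from .preprocess import (
    FeatureExtractor,
    RandomProjectionExtractor,
    crop_tiles,
    extract_features,
    tile,
    tissue_mask,
)
from .synthetic import SyntheticConfig, SyntheticSlide, assemble_slide, generate_dataset
from .training import SlideSample, TrainConfig, TrainResult, predict_table, train

__all__ = [
    "build_sample",
    "build_samples",
    "run_experiment",
    "save_checkpoint",
    "load_checkpoint",
]

#: masking pyramid level for synthetic slides: coarse enough to be cheap,
#: fine enough that one tile still spans many mask pixels
SYNTHETIC_MASK_LEVEL = 2
#: tissue-mask area threshold (level-SYNTHETIC_MASK_LEVEL pixels) for
#: desk-scale synthetic slides, where tissue spans only a few tiles
SYNTHETIC_MIN_AREA = 64


def build_sample(
    slide: SyntheticSlide,
    extractor: FeatureExtractor,
    knn_k: int = 5,
    dmin: float = 50.0,
    gray_levels: int = 8,
) -> SlideSample:
    """Preprocess one synthetic slide into a training sample.

    Tiles come from tissue extraction on the assembled image (not from
    the generator's tile list), so the whole preprocessing path is
    exercised; nucleus masks are matched to tiles by their recorded
    origins, tiles without a mask get no graph.
    """
    ts = slide.tiles[0].image.shape[0]
    img = assemble_slide(slide, rgb=True)
    ds = 2 ** SYNTHETIC_MASK_LEVEL
    tm = tissue_mask(
        img[::ds, ::ds],
        level=SYNTHETIC_MASK_LEVEL,
        min_area=SYNTHETIC_MIN_AREA,
        tile_size=ts,
    )
    ti = tile(tm, slide_dims=(img.shape[1], img.shape[0]), tile_size=ts)
    if len(ti) == 0:
        raise ValueError(f"no tissue tiles found in slide {slide.slide_id}")
    crops = crop_tiles(img, ti)
    bag = extract_features(crops, ti, extractor, slide_id=slide.slide_id, label=slide.label)
    by_origin = {t.origin: t for t in slide.tiles}
    graphs: list[NucleiGraph | None] = []
    for x, y in ti.coords:
        st = by_origin.get((int(x), int(y)))
        if st is None or st.instance_mask.max() == 0:
            graphs.append(None)
            continue
        table = feature_table(st.image, st.instance_mask, gray_levels=gray_levels)
        if len(table) == 0:
            graphs.append(None)
            continue
        graphs.append(
            build_knn_graph(
                table[["centroid_x", "centroid_y"]].to_numpy(),
                table[FEATURE_NAMES].to_numpy(),
                k=knn_k,
                dmin=dmin,
            )
        )
    return SlideSample(bag=bag, graphs=graphs, label=slide.label)


def build_samples(slides, extractor=None, **kwargs) -> list[SlideSample]:
    extractor = RandomProjectionExtractor() if extractor is None else extractor
    return [build_sample(s, extractor, **kwargs) for s in slides]


#: loss-weight variants of the ablation study: slide branch only, plus
#: patch penalty, plus nuclei penalty, and the full model; the partial
#: variants renormalize the remaining weights proportionally
ABLATION_WEIGHTS = {
    "full": (0.7, 0.2, 0.1),
    "ablation1": (1.0, 0.0, 0.0),
    "ablation2": (0.7 / 0.9, 0.2 / 0.9, 0.0),
    "ablation3": (0.7 / 0.8, 0.0, 0.1 / 0.8),
}


def run_experiment(
    seed: int = 0,
    synth_config: SyntheticConfig | None = None,
    train_config: TrainConfig | None = None,
    extractor: FeatureExtractor | None = None,
    samples: list[SlideSample] | None = None,
) -> dict:
    """Full synthetic study: generate -> preprocess -> train -> evaluate.

    Returns a dict with the train result, the test prediction table and
    the test :class:`MetricReport`.  Prebuilt ``samples`` (e.g. for
    ablation variants on the same dataset) skip the generation and
    preprocessing stages.
    """
    synth_config = replace(synth_config, seed=seed) if synth_config else SyntheticConfig(seed=seed)
    train_config = replace(train_config, seed=seed) if train_config else TrainConfig(seed=seed)
    if samples is None:
        slides = generate_dataset(synth_config)
        samples = build_samples(slides, extractor)
    else:
        slides = []
    result = train(samples, train_config)
    table = predict_table(result.model, samples, result.split["test"])
    report = metrics(confusion(table["GT"].to_numpy(), table["PreCls"].to_numpy()))
    return {
        "slides": slides,
        "samples": samples,
        "result": result,
        "predictions": table,
        "report": report,
    }


def ablation_report(
    seed: int = 0,
    variants: dict[str, tuple[float, float, float]] | None = None,
    synth_config: SyntheticConfig | None = None,
    train_config: TrainConfig | None = None,
    samples: list[SlideSample] | None = None,
) -> pd.DataFrame:
    """Test AC/SP/SE/PC per loss-weight variant, one row per method.

    All variants share the same dataset, split and initialization; only
    the loss weights differ, so the table isolates the contribution of
    the patch and nuclei penalties.
    """
    variants = dict(ABLATION_WEIGHTS) if variants is None else variants
    if samples is None:
        synth = replace(synth_config, seed=seed) if synth_config else SyntheticConfig(seed=seed)
        samples = build_samples(generate_dataset(synth))
    base = train_config or TrainConfig(seed=seed)
    rows = []
    for name, weights in variants.items():
        cfg = replace(base, seed=seed, weights=weights)
        run = run_experiment(seed=seed, train_config=cfg, samples=samples)
        rows.append({"method": name, **run["report"].to_dict()})
    return pd.DataFrame(rows).set_index("method")


def save_checkpoint(result: TrainResult, path: str | Path) -> None:
    """Weights + config + degree normalizer, as a compressed npz."""
    path = Path(path)
    state = result.model.state()
    arrays = {f"mil_{i}": a for i, a in enumerate(state["mil"])}
    arrays.update({f"gnn_{i}": a for i, a in enumerate(state["gnn"])})
    for key in ("patch_mean", "patch_std", "nuc_mean", "nuc_std"):
        if state[key] is not None:
            arrays[key] = state[key]
    meta = {"delta": state["delta"], "config": asdict(result.config), "best_epoch": result.best_epoch}
    np.savez_compressed(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path: str | Path):
    """Rebuild the model and config from :func:`save_checkpoint` output."""
    from .graph import NucleiGNN
    from .mil import AttentionMIL
    from .training import ConstrainedMILModel

    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        cfg = meta["config"]
        for key in ("weights", "split", "nuclei_per_tile"):
            if key in cfg and isinstance(cfg[key], list):
                cfg[key] = tuple(cfg[key])
        config = TrainConfig(**cfg)
        rng = np.random.default_rng(0)
        model = ConstrainedMILModel(
            mil=AttentionMIL(
                feature_dim=config.feature_dim,
                trunk_dim=config.trunk_dim,
                gate_dim=config.gate_dim,
                n_heads=config.n_heads,
                d_k=config.d_k,
                attention_variant=config.attention_variant,
                rng=rng,
            ),
            gnn=NucleiGNN(
                in_dim=16,
                hidden=config.gnn_hidden,
                msg_dim=config.gnn_msg_dim,
                n_layers=config.gnn_layers,
                rng=rng,
            ),
            delta=meta["delta"],
        )
        model.mil.load_state([z[f"mil_{i}"] for i in range(len(model.mil.parameters()))])
        model.gnn.load_state([z[f"gnn_{i}"] for i in range(len(model.gnn.parameters()))])
        for key in ("patch_mean", "patch_std", "nuc_mean", "nuc_std"):
            if key in z:
                setattr(model, key, z[key])
    return model, config
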