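"""Desk-scale evaluation protocols for the segmentation and mapping stages.

The production configuration (512x512 patches, 50 epochs, a 64-wide
encoder) is far beyond a single-CPU session, so the package defines two
fixed, seeded protocols that preserve the study design at reduced size:

* :func:`segmentation_benchmark` — train the SE network and the identically
  configured plain U-Net (no SE blocks) for 5 epochs on 200 synthetic
  128x128 patches with the production optimizer settings (Adam, learning
  rate 3e-4, batch size 4) and score both on 50 held-out patches.  This
  reproduces the SE-vs-plain comparison design, not any absolute score.
* :func:`mapping_benchmark` — generate a 6-section specimen case, jitter
  each section's placement, refine the layouts by cross-correlation, and
  score the rebuilt recovery map against the generator's ground truth.

All sampling is deterministic given ``seed``.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .loss_metrics import dice, miou, per_class_dice
from .mapping import build_recovery_map, refine_layout
from .model import NetworkConfig, build_network
from .synthetic import SynthParams, generate_case, generate_patches
from .training import TrainConfig, predict_batch, train

#: reduced network: ResNet-34 block layout at quarter width
BENCH_NET = dict(input_size=128, base_width=16, se_reduction=4)
#: production optimizer settings; augmentation shifts scaled to patch size
BENCH_TRAIN = dict(learning_rate=3e-4, epochs=5, batch_size=4,
                   shift_range=(0, 20))

N_TRAIN, N_TEST, PATCH = 200, 50, 128


def benchmark_patches(seed: int, n_train: int = N_TRAIN, n_test: int = N_TEST,
                      patch: int = PATCH):
    """Seeded train/test patch sets for the segmentation benchmark."""
    params = SynthParams(lesion_radius_range=(22, 45), rng_seed=seed)
    rng = np.random.default_rng(seed)
    return (
        generate_patches(params, n_train, patch, rng),
        generate_patches(params, n_test, patch, rng),
    )


def train_segmenter(train_set, seed: int, se_placement: str = "decoder",
                    epochs: int | None = None):
    """Train one benchmark network (SE or plain) on the given patches."""
    cfg = NetworkConfig(se_placement=se_placement, seed=seed + 1, **BENCH_NET)
    tcfg = TrainConfig(rng_seed=seed + 2, **BENCH_TRAIN)
    if epochs is not None:
        tcfg = replace(tcfg, epochs=epochs)
    net = build_network(cfg)
    log = train(net, train_set, tcfg)
    return net, log


def score_segmenter(net, test_set):
    """Per-patch mean MIoU and Dice on held-out patches."""
    probs = predict_batch(net, [p[0] for p in test_set])
    preds = probs.argmax(axis=1)
    K = net.cfg.num_classes
    mious = [miou(pr, cm, K) for pr, (_, cm) in zip(preds, test_set)]
    dices = [dice(pr, cm, K) for pr, (_, cm) in zip(preds, test_set)]
    return {
        "miou_mean": float(np.mean(mious)),
        "miou_sd": float(np.std(mious, ddof=1)),
        "dice_mean": float(np.mean(dices)),
        "dice_sd": float(np.std(dices, ddof=1)),
        "n": len(test_set),
    }


def segmentation_benchmark(seed: int, include_plain: bool = True) -> dict:
    """SE-vs-plain comparison at desk scale; returns per-model scores."""
    train_set, test_set = benchmark_patches(seed)
    out = {}
    net_se, log_se = train_segmenter(train_set, seed, "decoder")
    out["se"] = score_segmenter(net_se, test_set)
    out["se"]["final_loss"] = float(log_se["mean_loss"].iloc[-1])
    if include_plain:
        net_pl, log_pl = train_segmenter(train_set, seed, "none")
        out["plain"] = score_segmenter(net_pl, test_set)
        out["plain"]["final_loss"] = float(log_pl["mean_loss"].iloc[-1])
    return out


def mapping_case_params(seed: int) -> SynthParams:
    """Case geometry for the mapping benchmark: 6 strips, coarse working
    resolution so a strip is ~60 px tall, lesions large enough to survive
    photo-scale resampling."""
    return SynthParams(
        slide_size=(64, 400),
        n_cancer_lesions=3,
        n_metaplasia_lesions=3,
        lesion_radius_range=(20, 32),
        microns_per_pixel=40.0,
        photo_scale=0.6,
        rng_seed=seed,
    )


def mapping_benchmark(seed: int, n_sections: int = 6) -> dict:
    """Jitter -> refine -> rebuild protocol for the recovery map.

    Sections start from their nominal grid layouts (which differ from the
    rendered truth by the generator's +-10 px / +-3 deg jitter); refinement
    must recover the true placements and the rebuilt map must match the
    generator's ground-truth recovery map.
    """
    params = mapping_case_params(seed)
    case = generate_case(params, n_sections=n_sections)
    photo = case.specimen_photo
    errors, sections = [], []
    for sec in case.sections:
        res = refine_layout(sec.image, sec.layout_nominal, photo,
                            search_window=15)
        err = float(np.hypot(res.layout.anchor[0] - sec.layout_true.anchor[0],
                             res.layout.anchor[1] - sec.layout_true.anchor[1]))
        errors.append(err)
        sections.append((sec.class_map, res.layout))
    rec = build_recovery_map(sections, photo,
                             microns_per_pixel=params.microns_per_pixel)
    initial_errors = [
        float(np.hypot(s.layout_nominal.anchor[0] - s.layout_true.anchor[0],
                       s.layout_nominal.anchor[1] - s.layout_true.anchor[1]))
        for s in case.sections
    ]
    return {
        "translation_errors_px": errors,
        "max_translation_error_px": float(max(errors)),
        "mean_initial_error_px": float(np.mean(initial_errors)),
        "recovery_dice": float(dice(rec.class_canvas, case.gt_class_canvas, 3)),
        "recovery_miou": float(miou(rec.class_canvas, case.gt_class_canvas, 3)),
        "per_class_dice": [
            float(d)
            for d in per_class_dice(rec.class_canvas, case.gt_class_canvas, 3)
        ],
    }
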