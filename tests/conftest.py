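"""Shared fixtures: synthetic scenes and the tiny trained detector.

The detection scene (24 training + 6 held-out frames of 256x256 px with 15
bees) and the dense tracking scene (50 identities with painter's-order
occlusions) are the package's desk-scale study conditions; the trained
detector is session-scoped because training it takes a few CPU minutes.
"""

from __future__ import annotations

import numpy as np
import pytest

from combtrack import detector, simulator
from combtrack.targets import (SegmentationTarget, background_foreground_ratio,
                               render_bee_targets, render_weight_map)

N_TRAIN_FRAMES = 24
N_HELDOUT_FRAMES = 6


@pytest.fixture(scope="session")
def detection_scene():
    """(truth, frames) for the 256x256, 15-bee detection scene."""
    cfg = simulator.detection_scene_config(seed=0)
    truth = simulator.simulate_trajectories(cfg)
    frames = simulator.render_frames(truth)
    return truth, frames


@pytest.fixture(scope="session")
def tiny_detector_config():
    return detector.DetectorConfig(encoder_widths=(8, 16), recurrent=True,
                                   tile=256, tile_margin=32)


def train_detection_model(truth, frames, config, n_iter=45, lr=1e-3, seed=0,
                          n_train=N_TRAIN_FRAMES, angle_weight=0.2,
                          select_every=5, select_after=20):
    """Train a detector on the scene's first frames.

    Annotations of bees covered by a climb-over are omitted — a labeler
    cannot mark what is not visible. The angle loss is down-weighted so the
    orientation head does not crowd out class learning at this capacity.
    From ``select_after`` epochs on, the checkpoint with the best detection
    rates on a fixed subset of *training* frames is kept (ordinary model
    selection; held-out frames are never consulted).
    """
    import combtrack.nn as nn

    geom = truth.config.geometry
    shape = frames.shape[1:]
    anns = [truth.annotations(f, occlusion="body")
            for f in range(n_train)]
    tg = [render_bee_targets(a, shape, geom) for a in anns]
    ratio = background_foreground_ratio(tg)
    labeled = []
    for f in range(n_train):
        w = render_weight_map(anns[f], shape, geom, ratio)
        labeled.append((frames[f], SegmentationTarget(tg[f].class_map,
                                                      tg[f].angle_map, w)))
    model = detector.build_network(config, seed=seed)
    opt = nn.Adam(model.params(), lr=lr)
    select_frames = list(range(0, n_train, max(1, n_train // 6)))
    best_score, best_params = -np.inf, None
    done = 0
    while done < n_iter:
        step = min(select_every, n_iter - done)
        detector.fine_tune(model, labeled, n_iter=step, optimizer=opt,
                           angle_weight=angle_weight)
        done += step
        if done >= select_after:
            tpr, fpr = detection_rates(model, truth, frames, select_frames)
            score = tpr - fpr
            if score > best_score:
                best_score = score
                best_params = [p.value.copy() for p in model.params()]
    if best_params is not None:
        for p, v in zip(model.params(), best_params):
            p.value[...] = v
    return model


@pytest.fixture(scope="session")
def trained_tiny_detector(detection_scene, tiny_detector_config):
    """Detector trained on the scene's first 24 frames (held-out: last 6)."""
    truth, frames = detection_scene
    return train_detection_model(truth, frames, tiny_detector_config)


def detection_rates(model, truth, frames, frame_indices, match_radius=None):
    """TPR / FPR of a detector against simulator ground truth.

    A detection is a true positive when it lies within ``match_radius``
    (default: a quarter body length) of an unclaimed ground-truth bee; FPR is
    the fraction of detections that match no bee.
    """
    geom = truth.config.geometry
    radius = match_radius or geom.body_length / 4.0
    tp = fp = fn = 0
    prior = None
    for f in frame_indices:
        logits, ang, prior = model.forward(frames[f], prior)
        dets = detector.maps_to_detections(logits.argmax(0), ang, model.config,
                                           frame=f)
        anns = truth.annotations(f, occlusion="body")
        used: set[int] = set()
        for d in dets:
            cand = [(np.hypot(a.x - d.x, a.y - d.y), i)
                    for i, a in enumerate(anns) if i not in used]
            if cand and min(cand)[0] <= radius:
                used.add(min(cand)[1])
                tp += 1
            else:
                fp += 1
        fn += len(anns) - len(used)
    tpr = tp / max(1, tp + fn)
    fpr = fp / max(1, tp + fp)
    return tpr, fpr


@pytest.fixture(scope="session")
def tracking_scene():
    """(truth, detections-with-occlusion, oracle embeddings aligned to rows)."""
    cfg = simulator.tracking_scene_config(seed=1)
    truth = simulator.simulate_trajectories(cfg)
    # detections vanish when target blobs would merge (climb-over events)
    det = truth.detections(occlusion="body")
    emb = simulator.oracle_embeddings(truth)
    E = simulator.embeddings_for_detections(det, emb)
    return truth, det, E
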