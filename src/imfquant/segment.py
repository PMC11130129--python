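"""Fat segmentation: CIELAB k-means clustering and an encoder-decoder CNN.

Two segmenters are exposed behind a common ``FatPrediction`` result, both
clipped to the convex hull of the tissue mask.  The k-means route clusters
pixel colors in CIELAB (three clusters: fat, stained tissue, background)
and takes the brightest cluster as fat — fast and annotation-free, but
blind to texture, so white artifacts such as cracks inside the tissue are
picked up as fat.  The network route (``SegNetLite``) is trained on labeled
tiles and also sees local structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2lab
from sklearn.cluster import KMeans

from .errors import (ConfigurationError, DataError, DegenerateClusteringError,
                     EmptyMaskError, ModelStateError)
from .nn import Adam, SegNetLite, bce_with_logits
from .synth import SyntheticSection


@dataclass(frozen=True)
class KMeansConfig:
    """k-means color clustering settings.

    ``fat_rule`` selects the fat cluster: "max-lightness" takes the cluster
    with the highest L* centroid (adipocytes are unstained and near-white);
    an integer picks a cluster index manually.  ``fit_on_hull`` restricts
    the fit to hull pixels so the slide background does not dominate.
    """

    n_clusters: int = 3
    seed: int = 0
    restarts: int = 3
    fat_rule: str | int = "max-lightness"
    fit_on_hull: bool = True
    max_fit_pixels: int = 200_000

    def __post_init__(self) -> None:
        if self.n_clusters < 2:
            raise ConfigurationError("need at least 2 clusters")


@dataclass(frozen=True)
class SegnetConfig:
    """Architecture and training settings for the encoder-decoder net."""

    depth: int = 3
    channels: tuple[int, ...] = (8, 16, 32)
    tile: int = 256
    epochs: int = 15
    lr: float = 2e-3
    batch_size: int = 8
    seed: int = 0
    threshold: float = 0.5
    overlap: float = 0.5
    pos_weight: float = 3.0
    downsample: int = 2
    calibrate_threshold: bool = True
    lr_decay_at: float = 0.7
    lr_decay: float = 0.25
    grad_clip: float = 5.0
    max_restarts: int = 2
    restart_loss: float = 0.3

    def __post_init__(self) -> None:
        if len(self.channels) != self.depth:
            raise ConfigurationError("channels must list one width per level")
        if self.tile % (self.downsample * 2 ** self.depth):
            raise ConfigurationError(
                f"tile size {self.tile} not divisible by downsample * 2**depth")
        if not 0.0 <= self.overlap < 1.0:
            raise ConfigurationError("overlap must be in [0, 1)")


@dataclass
class FatPrediction:
    """Binary fat mask (subset of the hull) plus optional score raster."""

    fat: np.ndarray
    method: str
    score: np.ndarray | None = None


# ---------------------------------------------------------------------------
# k-means route


def kmeans_fat(image: np.ndarray, hull: np.ndarray,
               cfg: KMeansConfig | None = None) -> FatPrediction:
    """Cluster CIELAB colors and return the brightest cluster as fat.

    The model is fit on (a subsample of) hull-restricted pixels and applied
    to every hull pixel; the result is clipped to the hull.  Deterministic
    for a fixed seed.
    """
    cfg = cfg or KMeansConfig()
    hull = np.asarray(hull, dtype=bool)
    if not hull.any():
        raise EmptyMaskError("hull is empty; nothing to cluster")
    lab = rgb2lab(image)
    region = hull if cfg.fit_on_hull else np.ones_like(hull)
    pixels = lab[region].reshape(-1, 3)
    n_unique = np.unique(pixels, axis=0).shape[0]
    if n_unique < cfg.n_clusters:
        raise DegenerateClusteringError(
            f"{n_unique} distinct colors < {cfg.n_clusters} clusters")
    rng = np.random.default_rng(cfg.seed)
    fit_px = pixels
    if len(pixels) > cfg.max_fit_pixels:
        fit_px = pixels[rng.choice(len(pixels), cfg.max_fit_pixels, replace=False)]
    km = KMeans(n_clusters=cfg.n_clusters, n_init=cfg.restarts,
                random_state=cfg.seed)
    km.fit(fit_px)
    if cfg.fat_rule == "max-lightness":
        fat_cluster = int(np.argmax(km.cluster_centers_[:, 0]))
    else:
        fat_cluster = int(cfg.fat_rule)
    hull_labels = km.predict(lab[hull].reshape(-1, 3))
    fat = np.zeros_like(hull)
    fat[hull] = hull_labels == fat_cluster
    return FatPrediction(fat=fat & hull, method="kmeans")


# ---------------------------------------------------------------------------
# network route


def build_segnet(cfg: SegnetConfig | None = None) -> SegNetLite:
    """Instantiate an untrained encoder-decoder per the config."""
    cfg = cfg or SegnetConfig()
    return SegNetLite(depth=cfg.depth, channels=cfg.channels, seed=cfg.seed)


def extract_tiles(sections: list[SyntheticSection], n_tiles: int, tile: int,
                  seed: int, min_tissue_frac: float = 0.3,
                  background_frac: float = 0.15):
    """Random labeled tile crops (X (N,3,t,t) in [0,1], Y (N,t,t) in {0,1}).

    Most crops are resampled until they contain at least ``min_tissue_frac``
    tissue so the fat/tissue interface dominates training; a
    ``background_frac`` share is deliberately drawn with as little tissue as
    possible so the net also learns that bare slide background is not fat.
    """
    if not sections:
        raise DataError("no sections to sample tiles from")
    rng = np.random.default_rng(seed)
    X = np.empty((n_tiles, 3, tile, tile), dtype=np.float64)
    Y = np.empty((n_tiles, tile, tile), dtype=np.float64)
    for i in range(n_tiles):
        want_background = rng.random() < background_frac
        best = None
        for _attempt in range(6):
            s = sections[rng.integers(len(sections))]
            h, w = s.truth_tissue.shape
            if h < tile or w < tile:
                raise DataError(f"section {s.truth_tissue.shape} smaller than tile {tile}")
            y0 = int(rng.integers(h - tile + 1))
            x0 = int(rng.integers(w - tile + 1))
            frac = s.truth_tissue[y0:y0 + tile, x0:x0 + tile].mean()
            key = frac if want_background else -frac
            if best is None or key < best[0]:
                best = (key, s, y0, x0)
            if (want_background and frac < 0.05) or \
                    (not want_background and frac >= min_tissue_frac):
                break
        _, s, y0, x0 = best
        X[i] = np.moveaxis(
            s.image[y0:y0 + tile, x0:x0 + tile].astype(np.float64) / 255.0, -1, 0)
        Y[i] = s.truth_fat[y0:y0 + tile, x0:x0 + tile]
    return X, Y


def _block_reduce(a: np.ndarray, s: int) -> np.ndarray:
    """Mean over s x s blocks of the trailing two axes."""
    if s == 1:
        return a
    sh = a.shape
    a = a.reshape(*sh[:-2], sh[-2] // s, s, sh[-1] // s, s)
    return a.mean(axis=(-3, -1))


def train_segnet(model: SegNetLite, tiles, cfg: SegnetConfig | None = None) -> SegNetLite:
    """Minimize binary cross-entropy with Adam; records ``model.history``.

    ``tiles`` is an (X, Y) pair as produced by :func:`extract_tiles`.
    Training is deterministic for a fixed config seed (shuffling and weight
    initialization both derive from explicit seeds).  The learning rate is
    stepped down late in the schedule, and afterwards the binarization
    threshold is calibrated on the training tiles so the aggregate predicted
    fat fraction matches the label fraction (stored as ``model.threshold``).
    """
    cfg = cfg or SegnetConfig()
    X, Y = tiles
    if len(X) == 0:
        raise DataError("empty tile set")
    if cfg.downsample > 1:
        X = _block_reduce(X, cfg.downsample)
        Y = (_block_reduce(Y, cfg.downsample) >= 0.5).astype(np.float64)
    n = len(X)
    # hold out a validation slice for threshold calibration: training-tile
    # probabilities saturate once memorized and would bias the quantile
    n_val = int(round(0.15 * n)) if cfg.calibrate_threshold and n >= 10 else 0
    split_rng = np.random.default_rng(cfg.seed + 1)
    perm = split_rng.permutation(n)
    val_idx, fit_idx = perm[:n_val], perm[n_val:]
    Xf, Yf = X[fit_idx], Y[fit_idx]
    nf = len(Xf)

    def _fit(seed: int):
        init = SegNetLite(depth=model.depth, channels=model.channels,
                          in_channels=model.in_channels, seed=seed)
        params = init.params
        rng = np.random.default_rng(seed + 1)
        opt = Adam(params, lr=cfg.lr)
        history: list[float] = []
        best = (np.inf, None)
        for epoch in range(cfg.epochs):
            if epoch == int(cfg.lr_decay_at * cfg.epochs):
                opt.lr = cfg.lr * cfg.lr_decay
            order = rng.permutation(nf)
            losses = []
            for start in range(0, nf, cfg.batch_size):
                sel = order[start:start + cfg.batch_size]
                model.params = params
                logits, cache = model.forward(Xf[sel], want_cache=True)
                loss, dlogits = bce_with_logits(logits, Yf[sel], cfg.pos_weight)
                grads = model.backward(cache, dlogits)
                if cfg.grad_clip:
                    norm = np.sqrt(sum(float((g * g).sum())
                                       for g in grads.values()))
                    if norm > cfg.grad_clip:
                        grads = {k: g * (cfg.grad_clip / norm)
                                 for k, g in grads.items()}
                opt.step(grads)
                losses.append(loss)
            epoch_loss = float(np.mean(losses))
            history.append(epoch_loss)
            if epoch_loss < best[0]:
                best = (epoch_loss, {k: v.copy() for k, v in params.items()})
        return best, history

    # Adam occasionally destabilizes and falls back to the constant-
    # prediction saddle; keep the best epoch and restart deterministically
    # if the fit never left the saddle
    best_overall = (np.inf, None, [])
    for attempt in range(cfg.max_restarts + 1):
        (best_loss, best_params), history = _fit(cfg.seed + 7919 * attempt)
        if best_loss < best_overall[0]:
            best_overall = (best_loss, best_params, history)
        if best_overall[0] < cfg.restart_loss:
            break
    model.params = best_overall[1]
    model.history = best_overall[2]
    model.trained = True
    model.downsample = cfg.downsample
    if n_val:
        Xv, Yv = X[val_idx], Y[val_idx]
        probs = np.concatenate([
            model.predict_proba(Xv[i:i + cfg.batch_size]).ravel()
            for i in range(0, len(Xv), cfg.batch_size)])
        target = float(np.mean(Yv))
        if 0.0 < target < 1.0:
            thr = float(np.quantile(probs, 1.0 - target))
            model.threshold = float(np.clip(thr, 0.05, 0.95))
    return model


class SegNetEnsemble:
    """Average the score maps of independently initialized networks.

    Behaves like a single model for inference (``predict_proba``,
    ``trained``, ``threshold``); reduces the per-section variance of the
    estimated fat fraction.
    """

    def __init__(self, members: list[SegNetLite]):
        if not members:
            raise DataError("ensemble needs at least one member")
        self.members = members
        self.threshold: float | None = None

    @property
    def trained(self) -> bool:
        return all(getattr(m, "trained", False) for m in self.members)

    @property
    def n_parameters(self) -> int:
        return sum(m.n_parameters for m in self.members)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        out = self.members[0].predict_proba(x)
        for m in self.members[1:]:
            out += m.predict_proba(x)
        return out / len(self.members)


def train_segnet_ensemble(tiles, cfg: SegnetConfig,
                          n_members: int = 2) -> SegNetEnsemble:
    """Train ``n_members`` networks from distinct seeds on the same tiles."""
    from dataclasses import replace

    members = []
    for k in range(n_members):
        mcfg = replace(cfg, seed=cfg.seed + 101 * k)
        member = build_segnet(mcfg)
        train_segnet(member, tiles, mcfg)
        members.append(member)
    return SegNetEnsemble(members)


def calibrate_threshold_on_sections(model: SegNetLite,
                                    sections: list[SyntheticSection],
                                    cfg: "SegnetConfig") -> float:
    """Set the binarization threshold from held-out labeled sections.

    Scores every section through the real tiled inference path and picks
    the threshold at which the aggregate predicted fat fraction over the
    true tissue area equals the true aggregate fraction.  More faithful
    than tile-level calibration because the score distribution of
    overlap-averaged whole-section inference differs from that of the
    tissue-rich training crops.  Stores and returns ``model.threshold``.
    """
    if not sections:
        raise DataError("no calibration sections")
    model.threshold = None  # score maps only; threshold irrelevant here
    matched = []
    for sec in sections:
        pred = segnet_fat(model, sec.image, sec.truth_tissue, cfg)
        scores = pred.score[sec.truth_tissue]
        frac = sec.truth_fat.sum() / sec.truth_tissue.sum()
        if 0.0 < frac < 1.0:
            # threshold at which this section's predicted fraction is exact
            matched.append(float(np.quantile(scores, 1.0 - frac)))
    if not matched:
        model.threshold = cfg.threshold
        return model.threshold
    # median across sections: robust to outlier sections and independent of
    # section size
    model.threshold = float(np.clip(np.median(matched), 0.05, 0.95))
    return model.threshold


def _tile_grid(extent: int, tile: int, stride: int) -> list[int]:
    if extent <= tile:
        return [0]
    starts = list(range(0, extent - tile + 1, stride))
    if starts[-1] != extent - tile:
        starts.append(extent - tile)
    return starts


def segnet_fat(model: SegNetLite, image: np.ndarray, hull: np.ndarray,
               cfg: SegnetConfig | None = None) -> FatPrediction:
    """Tiled whole-section inference, score-averaged in overlaps.

    The image is covered by ``tile``-sized windows with the configured
    overlap; per-pixel probabilities are averaged where windows overlap,
    thresholded, and clipped to the hull.
    """
    cfg = cfg or SegnetConfig()
    if not getattr(model, "trained", False):
        raise ModelStateError("model has not been trained (or loaded)")
    hull = np.asarray(hull, dtype=bool)
    h, w = hull.shape
    if not hull.any():
        return FatPrediction(fat=np.zeros((h, w), dtype=bool), method="segnet",
                             score=np.zeros((h, w)))
    s = cfg.downsample
    tile = cfg.tile // s
    stride = max(1, int(round(tile * (1.0 - cfg.overlap))))
    img = np.asarray(image, dtype=np.float64) / 255.0
    pad_h = (-h) % s
    pad_w = (-w) % s
    if pad_h or pad_w:
        img = np.pad(img, ((0, pad_h), (0, pad_w), (0, 0)), mode="reflect")
    img = _block_reduce(np.moveaxis(img, -1, 0), s)  # (3, H/s, W/s)
    ch, cw = img.shape[1:]
    tpad_h = max(0, tile - ch)
    tpad_w = max(0, tile - cw)
    if tpad_h or tpad_w:
        img = np.pad(img, ((0, 0), (0, tpad_h), (0, tpad_w)), mode="reflect")
    ph, pw = img.shape[1:]
    score = np.zeros((ph, pw))
    weight = np.zeros((ph, pw))
    x = img[None]
    for y0 in _tile_grid(ph, tile, stride):
        for x0 in _tile_grid(pw, tile, stride):
            prob = model.predict_proba(x[:, :, y0:y0 + tile, x0:x0 + tile])[0]
            score[y0:y0 + tile, x0:x0 + tile] += prob
            weight[y0:y0 + tile, x0:x0 + tile] += 1.0
    score = (score / weight)[:ch, :cw]
    score = np.repeat(np.repeat(score, s, axis=0), s, axis=1)[:h, :w]
    threshold = getattr(model, "threshold", None) or cfg.threshold
    fat = (score >= threshold) & hull
    return FatPrediction(fat=fat, method="segnet", score=score)
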