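"""Unified detection-tracking heads: heatmap/box/offset branches, displacement
prediction, learned affinity with Hungarian matching, cross-modal confidence
fusion and the multi-task loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment

from .autodiff import Tensor, as_tensor, concat, maximum, minimum
from .nn import Conv2d, Linear, Module

__all__ = ["DetectionOutput", "Detection", "AffinityMatrix", "MatchSet",
           "LossBundle", "DetectionHead", "decode_detections",
           "DisplacementNet", "AffinityNet", "match", "fuse_confidence",
           "compute_losses", "render_heatmap_target"]


# ----------------------------------------------------------------------
# domain types
# ----------------------------------------------------------------------

@dataclass
class DetectionOutput:
    heatmap: Tensor        # (1, H, W) in (0, 1)
    boxes: Tensor          # (4, H, W): centre x, y (grid cells) and w, h (px)
    offsets: Tensor        # (2, H, W) in (-1, 1)


@dataclass
class Detection:
    center: tuple[float, float]          # image pixels
    box: tuple[float, float, float, float]  # left, top, w, h in image pixels
    score: float
    conf_a: float = 1.0
    conf_m: float = 1.0
    fused_score: float | None = None
    embedding: np.ndarray | None = None


@dataclass
class AffinityMatrix:
    scores: np.ndarray     # raw s_ij
    affinity: np.ndarray   # sigmoid(s_ij) in (0, 1)


@dataclass
class MatchSet:
    pairs: list[tuple[int, int]]
    unmatched_detections: list[int]
    unmatched_tracks: list[int]


@dataclass
class LossBundle:
    center: Tensor
    box: Tensor
    refine: Tensor
    displacement: Tensor
    match: Tensor
    total: Tensor = field(init=False)

    def __post_init__(self):
        self.total = (self.center + self.box + self.refine
                      + self.displacement + self.match)


# ----------------------------------------------------------------------
# heads
# ----------------------------------------------------------------------

class DetectionHead(Module):
    """Three convolutional branches over the fused query grid:

    H = sigmoid(Conv3x3(ReLU(Conv1x1(x))))
    B = Conv1x1(ReLU(Conv3x3(x)))
    O = tanh(Conv1x1(ReLU(Conv3x3(x))))
    """

    def __init__(self, hidden: int, rng: np.random.Generator, mid: int | None = None):
        mid = mid or hidden
        self.h1 = Conv2d(hidden, mid, 1, rng)
        self.h2 = Conv2d(mid, 1, 3, rng, padding=1)
        self.b1 = Conv2d(hidden, mid, 3, rng, padding=1)
        self.b2 = Conv2d(mid, 4, 1, rng)
        self.o1 = Conv2d(hidden, mid, 3, rng, padding=1)
        self.o2 = Conv2d(mid, 2, 1, rng)

    def forward(self, grid) -> DetectionOutput:
        grid = as_tensor(grid)
        heat = self.h2(self.h1(grid).relu()).sigmoid()
        boxes = self.b2(self.b1(grid).relu())
        offs = self.o2(self.o1(grid).relu()).tanh()
        return DetectionOutput(heatmap=heat, boxes=boxes, offsets=offs)


def queries_to_grid(queries: Tensor, hs: int, ws: int) -> Tensor:
    """(N, h) row-major tokens -> (h, hs, ws) grid."""
    return as_tensor(queries).T.reshape(-1, hs, ws)


def decode_detections(out: DetectionOutput, score_thresh: float = 0.3,
                      max_det: int = 50, ratio: float = 4.0,
                      conf_maps: tuple[np.ndarray, np.ndarray] | None = None
                      ) -> list[Detection]:
    """Peak extraction: 3x3 local maxima of the heatmap above threshold,
    top ``max_det`` by score; centres refined by the offset branch; box size
    read at the peak.  Ties break by (score desc, y asc, x asc).
    """
    if not (0.0 < score_thresh < 1.0):
        raise ValueError("score_thresh must be in (0, 1)")
    heat = out.heatmap.data[0]
    boxes = out.boxes.data
    offs = out.offsets.data
    peaks = (heat == ndimage.maximum_filter(heat, size=3, mode="constant")) \
        & (heat > score_thresh)
    ys, xs = np.nonzero(peaks)
    order = sorted(range(len(ys)), key=lambda i: (-heat[ys[i], xs[i]], ys[i], xs[i]))
    dets: list[Detection] = []
    for i in order[:max_det]:
        y, x = int(ys[i]), int(xs[i])
        cx = (x + 0.5 + offs[0, y, x]) * ratio
        cy = (y + 0.5 + offs[1, y, x]) * ratio
        w = max(float(boxes[2, y, x]), 0.0)
        h = max(float(boxes[3, y, x]), 0.0)
        ca, cm = 1.0, 1.0
        if conf_maps is not None:
            ca = float(np.clip(conf_maps[0][y, x], 0.0, 1.0))
            cm = float(np.clip(conf_maps[1][y, x], 0.0, 1.0))
        dets.append(Detection(center=(cx, cy),
                              box=(cx - w / 2, cy - h / 2, w, h),
                              score=float(heat[y, x]), conf_a=ca, conf_m=cm))
    return dets


class DisplacementNet(Module):
    """Two-layer perceptron h -> 2h -> 2 predicting per-track displacement."""

    def __init__(self, hidden: int, rng: np.random.Generator):
        self.fc1 = Linear(hidden, 2 * hidden, rng)
        self.fc2 = Linear(2 * hidden, 2, rng, zero_init=True)
        self.hidden = hidden

    def forward(self, memory) -> Tensor:
        memory = as_tensor(memory)
        if memory.shape[-1] != self.hidden:
            raise ValueError(f"expected hidden width {self.hidden}, "
                             f"got {memory.shape[-1]}")
        return self.fc2(self.fc1(memory).relu())


class AffinityNet(Module):
    """Pairwise affinity from [U; V; U*V; |U-V|] through a two-layer network.

    The final layer is zero-initialised so an untrained network scores every
    pair sigmoid(0) = 0.5.
    """

    def __init__(self, hidden: int, rng: np.random.Generator, mid: int | None = None):
        mid = mid or hidden
        self.fc1 = Linear(4 * hidden, mid, rng)
        self.fc2 = Linear(mid, 1, rng, zero_init=True)
        self.hidden = hidden

    def forward(self, U, V) -> Tensor:
        """U: (Nd, h) detection embeddings; V: (Nt, h) track embeddings.
        Returns raw scores (Nd, Nt)."""
        U, V = as_tensor(U), as_tensor(V)
        nd, nt = U.shape[0], V.shape[0]
        Ue = U.reshape(nd, 1, self.hidden) + Tensor(np.zeros((nd, nt, self.hidden)))
        Ve = V.reshape(1, nt, self.hidden) + Tensor(np.zeros((nd, nt, self.hidden)))
        feats = concat([Ue, Ve, Ue * Ve, (Ue - Ve).abs()], axis=2)
        flat = feats.reshape(nd * nt, 4 * self.hidden)
        return self.fc2(self.fc1(flat).relu()).reshape(nd, nt)

    def affinity(self, U, V) -> AffinityMatrix:
        s = self.forward(U, V).data
        return AffinityMatrix(scores=s, affinity=1.0 / (1.0 + np.exp(-s)))


def match(A: AffinityMatrix | np.ndarray, accept_thresh: float = 0.3,
          score_bonus: np.ndarray | None = None) -> MatchSet:
    """Maximum-total-affinity one-to-one assignment via the Hungarian
    algorithm; pairs below ``accept_thresh`` (or excluded by a -inf bonus)
    are moved to the unmatched lists afterwards.

    ``score_bonus`` is an optional additive term used by the tracker for
    motion gating/tie-breaking; -inf entries forbid a pair outright.
    """
    aff = A.affinity if isinstance(A, AffinityMatrix) else np.asarray(A, float)
    if not np.all(np.isfinite(aff)):
        raise ValueError("affinity matrix must be finite")
    nd, nt = aff.shape
    total = aff.copy()
    if score_bonus is not None:
        total = total + score_bonus
    feasible = np.isfinite(total)
    cost = np.where(feasible, -total, 1e6)
    pairs = []
    if nd and nt:
        ri, ci = linear_sum_assignment(cost)
        for i, j in zip(ri, ci):
            if feasible[i, j] and aff[i, j] >= accept_thresh:
                pairs.append((int(i), int(j)))
    matched_d = {i for i, _ in pairs}
    matched_t = {j for _, j in pairs}
    return MatchSet(pairs=sorted(pairs),
                    unmatched_detections=[i for i in range(nd) if i not in matched_d],
                    unmatched_tracks=[j for j in range(nt) if j not in matched_t])


def fuse_confidence(det_score: float, c_a: float, c_m: float,
                    gamma: float = 2.0, eps: float = 1e-6) -> float:
    """Harmonic-mean cross-modal fusion:
    c_h = 2 c_a c_m / (c_a + c_m + eps); fused = score * sigmoid(gamma * c_h).
    """
    c_h = 2.0 * c_a * c_m / (c_a + c_m + eps)
    return det_score / (1.0 + np.exp(-gamma * c_h))


# ----------------------------------------------------------------------
# training targets and losses
# ----------------------------------------------------------------------

def render_heatmap_target(shape: tuple[int, int], centers: np.ndarray,
                          radii: np.ndarray) -> np.ndarray:
    """CenterNet-style Gaussian target heatmap on the stage grid."""
    H, W = shape
    ys, xs = np.mgrid[0:H, 0:W].astype(np.float64)
    target = np.zeros((H, W))
    for (cx, cy), r in zip(centers, radii):
        s = max(r / 3.0, 0.6)
        g = np.exp(-((xs - cx) ** 2 + (ys - cy) ** 2) / (2.0 * s * s))
        target = np.maximum(target, g)
    return target


def _focal_loss(heat: Tensor, target: np.ndarray, alpha: float, beta: float,
                eps: float = 1e-6) -> Tensor:
    """Penalty-reduced pixelwise focal loss on the centre heatmap."""
    p = heat.reshape(target.shape)
    p = p * (1.0 - 2.0 * eps) + eps
    pos = (target >= 1.0 - 1e-9).astype(float)
    neg_w = (1.0 - target) ** beta
    pos_term = ((1.0 - p) ** alpha) * p.log() * pos
    neg_term = (p ** alpha) * (1.0 - p).log() * neg_w * (1.0 - pos)
    n_pos = max(pos.sum(), 1.0)
    return -(pos_term + neg_term).sum() * (1.0 / n_pos)


def _smooth_l1(pred: Tensor, target: np.ndarray) -> Tensor:
    d = (pred - Tensor(target)).abs()
    small = (d.data < 1.0).astype(float)   # piecewise switch, constant w.r.t. grad
    per = d * d * 0.5 * small + (d - 0.5) * (1.0 - small)
    return per.sum() * (1.0 / max(target.size, 1))


def _iou_loss(pred_boxes: Tensor, gt_boxes: np.ndarray) -> Tensor:
    """1 - IoU between (n, 4) (left, top, w, h) boxes, averaged."""
    gt = Tensor(gt_boxes)
    n = gt_boxes.shape[0]
    px0, py0 = pred_boxes[:, 0], pred_boxes[:, 1]
    px1, py1 = px0 + pred_boxes[:, 2], py0 + pred_boxes[:, 3]
    gx0, gy0 = gt[:, 0], gt[:, 1]
    gx1, gy1 = gx0 + gt[:, 2], gy0 + gt[:, 3]
    iw = maximum(minimum(px1, gx1) - maximum(px0, gx0), Tensor(np.zeros(n)))
    ih = maximum(minimum(py1, gy1) - maximum(py0, gy0), Tensor(np.zeros(n)))
    inter = iw * ih
    union = (px1 - px0) * (py1 - py0) + (gx1 - gx0) * (gy1 - gy0) - inter
    iou = inter / (union + 1e-9)
    return (1.0 - iou).sum() * (1.0 / max(n, 1))


def _bce_logits(scores: Tensor, labels: np.ndarray) -> Tensor:
    """Stable binary cross-entropy on raw scores: softplus(s) - y*s, averaged."""
    y = Tensor(labels)
    per = scores.softplus() - y * scores
    return per.sum() * (1.0 / max(labels.size, 1))


def compute_losses(heat: Tensor, boxes_at_centers: Tensor, offsets_at_centers: Tensor,
                   heat_target: np.ndarray, box_target: np.ndarray,
                   offset_target: np.ndarray, displaced_boxes: Tensor,
                   gt_boxes: np.ndarray, match_scores: Tensor,
                   match_labels: np.ndarray, focal_alpha: float = 2.0,
                   focal_beta: float = 4.0) -> LossBundle:
    """Multi-task loss: centre focal + SmoothL1 boxes + L1 offsets +
    (1 - IoU) displacement + BCE association, summed with unit weights.
    """
    if heat.reshape(-1).shape[0] != heat_target.size:
        raise ValueError("heatmap/target shape mismatch")
    if boxes_at_centers.shape != box_target.shape:
        raise ValueError("box/target shape mismatch")
    l_cf = _focal_loss(heat, heat_target, focal_alpha, focal_beta)
    l_bs = _smooth_l1(boxes_at_centers, box_target)
    l_r = (offsets_at_centers - Tensor(offset_target)).abs().sum() \
        * (1.0 / max(offset_target.size, 1))
    l_td = _iou_loss(displaced_boxes, gt_boxes) if gt_boxes.size \
        else Tensor(0.0)
    l_match = _bce_logits(match_scores, match_labels) if match_labels.size \
        else Tensor(0.0)
    return LossBundle(center=l_cf, box=l_bs, refine=l_r,
                      displacement=l_td, match=l_match)
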