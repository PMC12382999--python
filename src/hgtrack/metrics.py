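"""CLEAR-MOT and identity metrics: MOTA, IDF1, Frag, IDSW, MT/ML.

Per-frame matching is IoU-based Hungarian assignment with the CLEAR
continuity convention (a ground-truth object keeps its previous frame's
prediction when that pairing is still above the IoU threshold).  IDF1 uses a
global, whole-sequence bipartite matching between identities.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .io_mot import MotRecord

__all__ = ["FrameAssignment", "MetricsReport", "box_iou", "assign_frames",
           "mota", "idf1", "fragments", "mt_ml", "evaluate"]


def box_iou(a, b) -> float:
    """IoU of two (left, top, width, height) boxes."""
    ax0, ay0, aw, ah = a
    bx0, by0, bw, bh = b
    ix = max(0.0, min(ax0 + aw, bx0 + bw) - max(ax0, bx0))
    iy = max(0.0, min(ay0 + ah, by0 + bh) - max(ay0, by0))
    inter = ix * iy
    union = aw * ah + bw * bh - inter
    return inter / union if union > 0 else 0.0


@dataclass
class FrameAssignment:
    frame: int
    matches: dict[int, int]        # gt id -> prediction id
    false_positives: list[int]     # unmatched prediction ids
    false_negatives: list[int]     # unmatched gt ids
    id_switches: list[int] = field(default_factory=list)  # gt ids that switched


@dataclass
class MetricsReport:
    mota: float
    idf1: float
    frag: int
    idsw: int
    mt: int
    ml: int
    idtp: int
    idfp: int
    idfn: int
    fp: int
    fn: int
    gt_total: int

    def as_dict(self) -> dict:
        return dict(MOTA=self.mota, IDF1=self.idf1, Frag=self.frag,
                    IDSW=self.idsw, MT=self.mt, ML=self.ml, IDTP=self.idtp,
                    IDFP=self.idfp, IDFN=self.idfn, FP=self.fp, FN=self.fn,
                    GT=self.gt_total)


def _by_frame(records: list[MotRecord]) -> dict[int, list[MotRecord]]:
    out: dict[int, list[MotRecord]] = defaultdict(list)
    for r in records:
        out[r.frame].append(r)
    return out


def assign_frames(gt: list[MotRecord], pred: list[MotRecord],
                  iou_thresh: float = 0.5) -> list[FrameAssignment]:
    """Per-frame GT-to-prediction matching with CLEAR continuity preference."""
    gt_f, pred_f = _by_frame(gt), _by_frame(pred)
    frames = sorted(set(gt_f) | set(pred_f))
    last_match: dict[int, int] = {}   # gt id -> last matched pred id (sticky)
    out: list[FrameAssignment] = []
    for t in frames:
        g = sorted(gt_f.get(t, []), key=lambda r: r.track_id)
        p = sorted(pred_f.get(t, []), key=lambda r: r.track_id)
        matches: dict[int, int] = {}
        used_p: set[int] = set()
        # 1) keep previous pairings still above threshold
        p_by_id = {r.track_id: r for r in p}
        for r in g:
            prev = last_match.get(r.track_id)
            if prev is not None and prev in p_by_id and prev not in used_p:
                if box_iou(r.box, p_by_id[prev].box) >= iou_thresh:
                    matches[r.track_id] = prev
                    used_p.add(prev)
        # 2) Hungarian on the rest, maximizing IoU
        g_rest = [r for r in g if r.track_id not in matches]
        p_rest = [r for r in p if r.track_id not in used_p]
        if g_rest and p_rest:
            iou = np.array([[box_iou(a.box, b.box) for b in p_rest] for a in g_rest])
            cost = np.where(iou >= iou_thresh, -iou, 1.0)
            ri, ci = linear_sum_assignment(cost)
            for i, j in zip(ri, ci):
                if iou[i, j] >= iou_thresh:
                    matches[g_rest[i].track_id] = p_rest[j].track_id
                    used_p.add(p_rest[j].track_id)
        switches = [gid for gid, pid in matches.items()
                    if gid in last_match and last_match[gid] != pid]
        for gid, pid in matches.items():
            last_match[gid] = pid
        out.append(FrameAssignment(
            frame=t, matches=matches,
            false_positives=sorted(r.track_id for r in p if r.track_id not in used_p),
            false_negatives=sorted(r.track_id for r in g if r.track_id not in matches),
            id_switches=sorted(switches)))
    return out


def mota(assignments: list[FrameAssignment]) -> float:
    """1 - (sum FP + sum FN + sum IDSW) / sum GT."""
    fp = sum(len(a.false_positives) for a in assignments)
    fn = sum(len(a.false_negatives) for a in assignments)
    idsw = sum(len(a.id_switches) for a in assignments)
    gt_total = sum(len(a.matches) + len(a.false_negatives) for a in assignments)
    if gt_total == 0:
        raise ZeroDivisionError("MOTA undefined: no ground-truth objects")
    return 1.0 - (fp + fn + idsw) / gt_total


def idf1(gt: list[MotRecord], pred: list[MotRecord],
         iou_thresh: float = 0.5) -> tuple[float, int, int, int]:
    """Identity F1: global bipartite matching between GT and predicted ids.

    Returns (idf1, idtp, idfp, idfn).
    """
    gt_f, pred_f = _by_frame(gt), _by_frame(pred)
    gt_ids = sorted({r.track_id for r in gt})
    pr_ids = sorted({r.track_id for r in pred})
    overlap = np.zeros((len(gt_ids), len(pr_ids)), dtype=np.int64)
    gi = {g: i for i, g in enumerate(gt_ids)}
    pi = {p: i for i, p in enumerate(pr_ids)}
    for t in set(gt_f) & set(pred_f):
        for a in gt_f[t]:
            for b in pred_f[t]:
                if box_iou(a.box, b.box) >= iou_thresh:
                    overlap[gi[a.track_id], pi[b.track_id]] += 1
    n_gt, n_pr = len(gt), len(pred)
    if n_gt == 0:
        raise ZeroDivisionError("IDF1 undefined: no ground-truth objects")
    idtp = 0
    if overlap.size:
        ri, ci = linear_sum_assignment(-overlap)
        idtp = int(overlap[ri, ci].sum())
    idfn = n_gt - idtp
    idfp = n_pr - idtp
    return 2.0 * idtp / (2.0 * idtp + idfp + idfn), idtp, idfp, idfn


def fragments(assignments: list[FrameAssignment]) -> int:
    """Count matched -> unmatched -> matched interruptions per GT trajectory."""
    status: dict[int, list[tuple[int, bool]]] = defaultdict(list)
    for a in assignments:
        for gid in a.matches:
            status[gid].append((a.frame, True))
        for gid in a.false_negatives:
            status[gid].append((a.frame, False))
    frag = 0
    for gid, seq in status.items():
        seq.sort()
        in_gap = False
        seen_match = False
        for _, matched in seq:
            if matched:
                if seen_match and in_gap:
                    frag += 1
                seen_match = True
                in_gap = False
            elif seen_match:
                in_gap = True
    return frag


def mt_ml(assignments: list[FrameAssignment],
          mt_frac: float = 0.8, ml_frac: float = 0.2) -> tuple[int, int]:
    """Mostly-tracked (matched >= 80% of lifespan frames, inclusive) and
    mostly-lost (<= 20%, inclusive) trajectory counts."""
    total: dict[int, int] = defaultdict(int)
    hit: dict[int, int] = defaultdict(int)
    for a in assignments:
        for gid in a.matches:
            total[gid] += 1
            hit[gid] += 1
        for gid in a.false_negatives:
            total[gid] += 1
    mt = sum(1 for gid, n in total.items() if hit[gid] >= mt_frac * n)
    ml = sum(1 for gid, n in total.items() if hit[gid] <= ml_frac * n)
    return mt, ml


def evaluate(gt: list[MotRecord], pred: list[MotRecord],
             iou_thresh: float = 0.5) -> MetricsReport:
    """Full metrics report for a GT/prediction record pair."""
    asg = assign_frames(gt, pred, iou_thresh)
    fp = sum(len(a.false_positives) for a in asg)
    fn = sum(len(a.false_negatives) for a in asg)
    idsw = sum(len(a.id_switches) for a in asg)
    gt_total = len(gt)
    f1, idtp, idfp, idfn = idf1(gt, pred, iou_thresh)
    mt, ml = mt_ml(asg)
    return MetricsReport(mota=mota(asg), idf1=f1, frag=fragments(asg),
                         idsw=idsw, mt=mt, ml=ml, idtp=idtp, idfp=idfp,
                         idfn=idfn, fp=fp, fn=fn, gt_total=gt_total)
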