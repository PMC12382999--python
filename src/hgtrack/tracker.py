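"""Frame-by-frame tracking orchestration and track lifecycle management.

The full pipeline per frame: motion decoupling -> dual-stream backbone ->
heterogeneous-graph fusion -> deformable memory decoding -> detection heads
with cross-modal confidence fusion -> gated affinity association (Hungarian)
-> re-detection of recently lost tracks -> lifecycle update.

A detector stub (any callable ``(frame_index, frame) -> list[Detection]``)
may replace the learned head, which enables oracle tests and ablations
without training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from . import motion as motion_mod
from .autodiff import Tensor, no_grad
from .backbone import Backbone, QueryProjector
from .config import RunConfig
from .head import (AffinityNet, Detection, DetectionHead, DisplacementNet,
                   compute_losses, decode_detections, fuse_confidence, match,
                   queries_to_grid, render_heatmap_target)
from .io_mot import MotRecord
from .mhgn import DeformableDecoder, GraphEncoder, build_graph
from .nn import AdamW, Module, cosine_warmup_lr
from .simulate import SimulatedSequence

log = logging.getLogger(__name__)

__all__ = ["TrackState", "Track", "TrackerState", "HGTModel", "Tracker",
           "oracle_detector_from_gt", "train_tiny", "save_checkpoint",
           "load_checkpoint"]


class TrackState(Enum):
    ACTIVE = "active"
    INACTIVE = "inactive"
    TERMINATED = "terminated"


@dataclass
class Track:
    track_id: int
    state: TrackState
    center: np.ndarray                       # (2,) last observed centre
    box: tuple[float, float, float, float]
    delta: np.ndarray                        # (2,) last displacement estimate
    mem_a: np.ndarray                        # (h,) appearance memory
    mem_m: np.ndarray                        # (h,) motion memory
    embedding: np.ndarray                    # (h,) association embedding
    history: dict[int, tuple] = field(default_factory=dict)  # frame -> box
    age: int = 0
    time_since_update: int = 0

    @property
    def predicted_center(self) -> np.ndarray:
        return self.center + self.delta * max(self.time_since_update, 1)


@dataclass
class TrackerState:
    tracks: list[Track] = field(default_factory=list)
    frame_index: int = 0
    next_id: int = 1

    def active(self) -> list[Track]:
        return [t for t in self.tracks if t.state is TrackState.ACTIVE]

    def inactive(self) -> list[Track]:
        return [t for t in self.tracks if t.state is TrackState.INACTIVE]


class HGTModel(Module):
    """The full learned model: dual backbones, query projection, graph
    encoder, deformable memory decoder, per-modality detection heads,
    displacement and affinity networks."""

    def __init__(self, cfg: RunConfig, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(cfg.seed)
        m = cfg.model
        self.cfg = cfg
        self.backbone_a = Backbone(1, m.widths, m.depths, rng)
        self.backbone_m = self.backbone_a if m.share_backbone \
            else Backbone(2, m.widths, m.depths, rng)
        self.proj_a = QueryProjector(m.widths, m.hidden, m.pe_bands, rng)
        self.proj_m = QueryProjector(m.widths, m.hidden, m.pe_bands, rng)
        self.encoder = GraphEncoder(m.hidden, cfg.mhgn.depth, rng,
                                    cfg.mhgn.spatial_cross)
        self.decoder = DeformableDecoder(m.hidden, rng, cfg.mhgn.decode_heads,
                                         cfg.mhgn.decode_points)
        self.head_a = DetectionHead(m.hidden, rng)
        self.head_m = DetectionHead(m.hidden, rng)
        self.disp_net = DisplacementNet(m.hidden, rng)
        self.affinity_net = AffinityNet(m.hidden, rng)

    # ------------------------------------------------------------------
    def forward(self, frame: np.ndarray, raster: np.ndarray, t_a, t_m,
                encode_depth: int | None = None):
        """Run backbone + fusion for one frame; returns per-stage fused
        grids for each modality plus refined memory blocks."""
        pyr_a = self.backbone_a(frame[None, :, :], "appearance")
        pyr_m = self.backbone_m(raster, "motion")
        stages = self.cfg.model.stages_used
        fused = {}
        mem_a, mem_m = t_a, t_m
        for s in stages:
            qa = self.proj_a(pyr_a, s)
            qm = self.proj_m(pyr_m, s)
            graph = build_graph(qa, qm, mem_a, mem_m, self.cfg.mhgn.k_spatial)
            out = self.encoder(graph, depth=encode_depth)
            c, hs, ws = pyr_a.stages[s].shape
            fused[s] = (out, hs, ws)
            mem_a, mem_m = out.t_a, out.t_m
        return fused

    def decode_memory(self, fused: dict, queries, ref_points: np.ndarray,
                      modality: str) -> Tensor:
        """Deformable-decode updated memory from all used stage grids."""
        out = None
        for s, (stage_out, hs, ws) in fused.items():
            grid_tokens = stage_out.d_a if modality == "appearance" else stage_out.d_m
            grid = grid_tokens.reshape(hs, ws, -1)
            term = self.decoder(queries, grid, ref_points)
            out = term if out is None else out + term
        return out * (1.0 / max(len(fused), 1))


def oracle_detector_from_gt(seq: SimulatedSequence, occlusion_iou: float | None = None,
                            embed_dim: int = 32, embed_seed: int = 0):
    """Build a perfect detector stub from simulator ground truth.

    Each agent id gets a fixed random unit embedding.  When ``occlusion_iou``
    is set, a detection is dropped whenever its box overlaps an earlier
    (lower-id) box above that IoU — emulating detector failure under
    occlusion.
    """
    from .metrics import box_iou

    rng = np.random.default_rng(embed_seed)
    ids = sorted(seq.trajectories)
    embeds = {i: (lambda v: v / np.linalg.norm(v))(rng.standard_normal(embed_dim))
              for i in ids}

    def detect(frame_index: int, frame: np.ndarray) -> list[Detection]:
        dets = []
        recs = seq.records[frame_index]
        kept: list[tuple] = []
        for (tid, left, top, w, h) in recs:
            box = (left, top, w, h)
            if occlusion_iou is not None and any(
                    box_iou(box, kb) > occlusion_iou for kb in kept):
                continue
            kept.append(box)
            dets.append(Detection(center=(left + w / 2, top + h / 2), box=box,
                                  score=0.99, conf_a=0.95, conf_m=0.95,
                                  embedding=embeds[tid].copy()))
        return dets

    return detect


class Tracker:
    """Online tracker over an ordered frame sequence."""

    def __init__(self, cfg: RunConfig | None = None, model: HGTModel | None = None,
                 detector=None):
        self.cfg = cfg or RunConfig()
        self.model = model
        if model is None and detector is None:
            self.model = HGTModel(self.cfg)
        self.detector = detector
        self.state = TrackerState()
        h = self.cfg.model.hidden

    # -- helpers -------------------------------------------------------
    def _detect_learned(self, frame: np.ndarray, prev_frame: np.ndarray):
        cfg = self.cfg
        if cfg.tracker.use_motion:
            raster, _, _ = motion_mod.decouple(prev_frame, frame, cfg.motion)
        else:
            raster = np.zeros((2,) + frame.shape)
        tracks = self.state.active() + self.state.inactive()
        h = cfg.model.hidden
        t_a = np.array([t.mem_a for t in tracks]).reshape(len(tracks), h)
        t_m = np.array([t.mem_m for t in tracks]).reshape(len(tracks), h)
        depth = None if cfg.tracker.use_mhgn else 0
        fused = self.model(frame, raster, t_a, t_m, encode_depth=depth)
        s0 = min(fused)
        out0, hs, ws = fused[s0]
        grid_a = queries_to_grid(out0.d_a, hs, ws)
        grid_m = queries_to_grid(out0.d_m, hs, ws)
        det_a = self.model.head_a(grid_a)
        det_m = self.model.head_m(grid_m)
        ratio = frame.shape[1] / ws
        heat_mean = Tensor(0.5 * (det_a.heatmap.data + det_m.heatmap.data))
        from .head import DetectionOutput
        merged = DetectionOutput(heatmap=heat_mean, boxes=det_a.boxes,
                                 offsets=det_a.offsets)
        dets = decode_detections(
            merged, cfg.head.score_thresh, cfg.head.max_det, ratio,
            conf_maps=(det_a.heatmap.data[0], det_m.heatmap.data[0]))
        # attach fused-query embeddings at the peak cells
        emb_grid = 0.5 * (out0.d_a.data + out0.d_m.data).reshape(hs, ws, -1)
        for d in dets:
            x = int(np.clip(d.center[0] / ratio, 0, ws - 1))
            y = int(np.clip(d.center[1] / ratio, 0, hs - 1))
            d.embedding = emb_grid[y, x].copy()
        return dets, fused, tracks, (hs, ws, ratio)

    def _predict_deltas(self, tracks: list[Track], fused=None, geom=None) -> None:
        """Update each track's delta estimate (learned MLP when a model is
        present, last observed velocity otherwise)."""
        if self.model is not None and tracks and fused is not None:
            h = self.cfg.model.hidden
            hs, ws, ratio = geom
            mem = np.array([0.5 * (t.mem_a + t.mem_m) for t in tracks])
            with no_grad():
                deltas = self.model.disp_net(mem).data
            for t, d in zip(tracks, deltas):
                # learned residual on top of the velocity prior
                t.delta = t.delta + d

    # -- core step -----------------------------------------------------
    def step(self, prev_frame: np.ndarray | None, frame: np.ndarray):
        """Process one frame; returns the list of (id, box, fused score)
        emitted for this frame."""
        cfg = self.cfg
        st = self.state
        k = st.frame_index
        fused = None
        geom = None
        if self.detector is not None:
            dets = self.detector(k, frame)
            tracks_fwd = st.active() + st.inactive()
        else:
            if prev_frame is None:
                prev_frame = frame
            if prev_frame.shape != frame.shape:
                raise ValueError("consecutive frames must share shape")
            with no_grad():
                dets, fused, tracks_fwd, geom = self._detect_learned(frame, prev_frame)
        # fused detection confidence
        for d in dets:
            d.fused_score = fuse_confidence(d.score, d.conf_a, d.conf_m,
                                            cfg.head.fusion_gamma,
                                            cfg.head.fusion_eps)
        # memory refresh through the deformable decoder
        if fused is not None and tracks_fwd:
            H, W = frame.shape
            refs = np.array([t.predicted_center for t in tracks_fwd]) \
                / np.array([W, H])
            refs = np.clip(refs, 0.0, 1.0)
            h = cfg.model.hidden
            mom = cfg.mhgn.mem_momentum
            with no_grad():
                for attr, modality in (("mem_a", "appearance"), ("mem_m", "motion")):
                    mem = np.array([getattr(t, attr) for t in tracks_fwd])
                    dec = self.model.decode_memory(fused, mem, refs, modality).data
                    for t, v in zip(tracks_fwd, dec):
                        setattr(t, attr, mom * getattr(t, attr) + (1 - mom) * v)
        active = st.active()
        self._predict_deltas(active, fused, geom)

        matched_tracks: set[int] = set()
        matched_dets: set[int] = set()
        emitted: list[tuple[int, tuple, float]] = []

        # association against active tracks (motion-gated affinity)
        if dets and active:
            U = np.array([d.embedding for d in dets])
            V = np.array([t.embedding for t in active])
            with no_grad():
                A = self._affinity(U, V)
            bonus = np.zeros_like(A.affinity)
            for i, d in enumerate(dets):
                for j, t in enumerate(active):
                    dist = float(np.hypot(d.center[0] - t.predicted_center[0],
                                          d.center[1] - t.predicted_center[1]))
                    if dist > cfg.tracker.gate_radius:
                        bonus[i, j] = -np.inf
                    else:
                        bonus[i, j] = -0.2 * dist / cfg.tracker.gate_radius
            ms = match(A, cfg.tracker.match_thresh, score_bonus=bonus)
            for i, j in ms.pairs:
                self._update_track(active[j], dets[i], k)
                matched_tracks.add(id(active[j]))
                matched_dets.add(i)
                emitted.append((active[j].track_id, dets[i].box, dets[i].fused_score))

        # lifecycle: unmatched active tracks go inactive immediately
        for t in active:
            if id(t) not in matched_tracks:
                t.state = TrackState.INACTIVE
                log.debug("frame %d: track %d inactive", k, t.track_id)

        # re-detection of recently lost tracks
        if cfg.tracker.use_redet:
            revived = self.redetect([d for i, d in enumerate(dets)
                                     if i not in matched_dets])
            for d, t in revived:
                self._update_track(t, d, k)
                matched_dets.add(dets.index(d))
                emitted.append((t.track_id, d.box, d.fused_score))
                log.debug("frame %d: track %d revived", k, t.track_id)

        # aging and termination of everything unmatched this frame
        for t in st.tracks:
            if t.state is TrackState.TERMINATED or t.history.get(k) is not None:
                continue
            t.time_since_update += 1
            if t.time_since_update > cfg.tracker.max_inactive_frames:
                t.state = TrackState.TERMINATED
                log.debug("frame %d: track %d terminated", k, t.track_id)

        # spawn new tracks from confident unmatched detections
        h = cfg.model.hidden
        for i, d in enumerate(dets):
            if i in matched_dets:
                continue
            if (d.fused_score or 0.0) >= cfg.tracker.spawn_score_thresh:
                emb = d.embedding if d.embedding is not None else np.zeros(h)
                t = Track(track_id=st.next_id, state=TrackState.ACTIVE,
                          center=np.array(d.center, float), box=d.box,
                          delta=np.zeros(2), mem_a=emb.copy(), mem_m=emb.copy(),
                          embedding=emb.copy(), history={k: d.box})
                st.next_id += 1
                st.tracks.append(t)
                emitted.append((t.track_id, d.box, d.fused_score))
                log.debug("frame %d: spawned track %d", k, t.track_id)

        # age inactive tracks that stayed unmatched this frame
        for t in st.inactive():
            if t.history.get(k) is None:
                t.time_since_update = t.time_since_update  # age tracked via tsu
        for t in st.tracks:
            t.age += 1
        st.frame_index += 1
        emitted.sort(key=lambda e: e[0])
        return emitted

    def _affinity(self, U: np.ndarray, V: np.ndarray):
        if self.model is not None:
            return self.model.affinity_net.affinity(U, V)
        # stub mode without a model: neutral affinity, gating decides
        from .head import AffinityMatrix
        s = np.zeros((len(U), len(V)))
        return AffinityMatrix(scores=s, affinity=1.0 / (1.0 + np.exp(-s)))

    def _update_track(self, t: Track, d: Detection, frame_index: int) -> None:
        new_center = np.array(d.center, float)
        gap = max(t.time_since_update, 1) if t.history else 1
        t.delta = (new_center - t.center) / gap
        t.center = new_center
        t.box = d.box
        t.history[frame_index] = d.box
        t.time_since_update = 0
        t.state = TrackState.ACTIVE
        if d.embedding is not None:
            mom = self.cfg.mhgn.mem_momentum
            t.embedding = mom * t.embedding + (1 - mom) * d.embedding
            if self.model is None:
                t.mem_a = t.embedding.copy()
                t.mem_m = t.embedding.copy()

    def redetect(self, unmatched_dets: list[Detection]) -> list[tuple[Detection, Track]]:
        """Affinity re-matching of unmatched detections against recently lost
        tracks, gated by motion consistency (detection must lie within the
        extrapolated position plus a radius)."""
        cfg = self.cfg
        lost = [t for t in self.state.inactive()
                if t.time_since_update <= cfg.tracker.max_inactive_frames]
        if not lost or not unmatched_dets:
            return []
        radius = cfg.tracker.gate_radius * cfg.tracker.redet_gate_scale
        U = np.array([d.embedding if d.embedding is not None
                      else np.zeros(cfg.model.hidden) for d in unmatched_dets])
        V = np.array([t.embedding for t in lost])
        with no_grad():
            A = self._affinity(U, V)
        bonus = np.zeros_like(A.affinity)
        for i, d in enumerate(unmatched_dets):
            for j, t in enumerate(lost):
                pred = t.predicted_center
                dist = float(np.hypot(d.center[0] - pred[0], d.center[1] - pred[1]))
                if dist > radius:
                    bonus[i, j] = -np.inf
                else:
                    bonus[i, j] = -0.2 * dist / radius
        ms = match(A, cfg.tracker.redet_thresh, score_bonus=bonus)
        return [(unmatched_dets[i], lost[j]) for i, j in ms.pairs]

    # ------------------------------------------------------------------
    def run(self, frames: list[np.ndarray]) -> list[MotRecord]:
        """Track a full sequence; returns MOTChallenge records (1-based)."""
        if len(frames) < 2:
            raise ValueError("need at least 2 frames")
        records: list[MotRecord] = []
        prev = None
        for k, frame in enumerate(frames):
            emitted = self.step(prev, frame)
            for tid, box, score in emitted:
                records.append(MotRecord(k + 1, tid, box[0], box[1],
                                         max(box[2], 1e-3), max(box[3], 1e-3),
                                         float(score or 0.0)))
            prev = frame
        return records


# ----------------------------------------------------------------------
# tiny training loop
# ----------------------------------------------------------------------

def _stage0_targets(seq: SimulatedSequence, k: int, hs: int, ws: int, ratio: float):
    recs = seq.records[k]
    centers, radii, boxes, offsets, cells = [], [], [], [], []
    for (tid, left, top, w, h) in recs:
        cx, cy = (left + w / 2) / ratio, (top + h / 2) / ratio
        ix, iy = int(np.clip(cx, 0, ws - 1)), int(np.clip(cy, 0, hs - 1))
        centers.append((cx - 0.5, cy - 0.5))
        radii.append(max(w, h) / ratio / 2)
        boxes.append((cx, cy, w, h))
        offsets.append((np.clip(cx - 0.5 - ix, -0.999, 0.999),
                        np.clip(cy - 0.5 - iy, -0.999, 0.999)))
        cells.append((iy, ix))
    heat = render_heatmap_target((hs, ws), np.array(centers), np.array(radii))
    for (iy, ix) in cells:
        heat[iy, ix] = 1.0
    return heat, np.array(boxes), np.array(offsets), cells, [r[0] for r in recs]


def train_tiny(seq: SimulatedSequence, cfg: RunConfig, steps: int = 200,
               model: HGTModel | None = None, warmup: int = 10,
               augment: bool = False, rng: np.random.Generator | None = None,
               log_every: int = 50) -> tuple[HGTModel, list[float]]:
    """Teacher-forced training on a simulated sequence.

    Walks consecutive frame pairs cyclically; each step supervises the
    detection heads (focal + SmoothL1 + L1), the displacement network
    (1 - IoU on displaced boxes) and the affinity network (BCE against the
    ground-truth identity assignment).  Returns the model and the per-step
    total losses.
    """
    if seq.n_frames < 2:
        raise ValueError("training sequence needs at least 2 frames")
    rng = rng or np.random.default_rng(cfg.seed)
    model = model or HGTModel(cfg, np.random.default_rng(cfg.seed))
    opt = AdamW(model.parameters(), lr=cfg.train.lr,
                weight_decay=cfg.train.weight_decay)
    h = cfg.model.hidden
    losses: list[float] = []

    # precompute motion rasters once (frozen inputs)
    rasters = [np.zeros((2,) + seq.frames[0].shape)]
    for k in range(1, seq.n_frames):
        r, _, _ = motion_mod.decouple(seq.frames[k - 1], seq.frames[k], cfg.motion)
        rasters.append(r)

    # persistent per-identity memory (teacher forcing), detached across frames
    id_mem: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    id_center: dict[int, tuple[float, float]] = {}
    id_box: dict[int, tuple] = {}

    pair_order = list(range(1, seq.n_frames))
    for step_i in range(steps):
        k = pair_order[step_i % len(pair_order)]
        frame, raster = seq.frames[k], rasters[k]
        flip = augment and cfg.train.flip and rng.random() < 0.5
        if flip:
            frame = frame[:, ::-1].copy()
            raster = raster[:, :, ::-1].copy()

        prev_ids = [r[0] for r in seq.records[k - 1]]
        t_a = np.array([id_mem[i][0] if i in id_mem else np.zeros(h)
                        for i in prev_ids]).reshape(len(prev_ids), h)
        t_m = np.array([id_mem[i][1] if i in id_mem else np.zeros(h)
                        for i in prev_ids]).reshape(len(prev_ids), h)

        fused = model(frame, raster, t_a, t_m)
        s0 = min(fused)
        out0, hs, ws = fused[s0]
        ratio = frame.shape[1] / ws
        grid_a = queries_to_grid(out0.d_a, hs, ws)
        grid_m = queries_to_grid(out0.d_m, hs, ws)
        det_a = model.head_a(grid_a)
        det_m = model.head_m(grid_m)

        if flip:
            # supervise against flipped ground truth
            W = frame.shape[1]
            recs = [(tid, W - left - w, top, w, h)
                    for (tid, left, top, w, h) in seq.records[k]]
            tmp = SimulatedSequence(frames=[frame], records=[recs],
                                    trajectories={}, impulse_count=0,
                                    config=seq.config)
            heat_t, box_t, off_t, cells, cur_ids = _stage0_targets(tmp, 0, hs, ws, ratio)
        else:
            heat_t, box_t, off_t, cells, cur_ids = _stage0_targets(seq, k, hs, ws, ratio)

        iy = np.array([c[0] for c in cells])
        ix = np.array([c[1] for c in cells])
        boxes_at = stack_channels(det_a.boxes, iy, ix)      # (n, 4)
        offs_at = stack_channels(det_a.offsets, iy, ix)     # (n, 2)
        boxes_at_m = stack_channels(det_m.boxes, iy, ix)
        offs_at_m = stack_channels(det_m.offsets, iy, ix)

        # displacement branch: predicted delta moves the previous gt box
        both = [i for i in cur_ids if i in prev_ids and i in id_box and not flip]
        if both:
            mem = np.array([0.5 * (id_mem[i][0] + id_mem[i][1]) for i in both])
            deltas = model.disp_net(mem)
            prev_boxes = np.array([id_box[i] for i in both], float)
            cur_map = {r[0]: r[1:] for r in seq.records[k]}
            gt_boxes = np.array([cur_map[i] for i in both], float)
            from .autodiff import concat as cat
            disp_boxes = cat([deltas[:, 0].reshape(-1, 1) + prev_boxes[:, 0:1],
                              deltas[:, 1].reshape(-1, 1) + prev_boxes[:, 1:2],
                              Tensor(prev_boxes[:, 2:4])], axis=1)
        else:
            disp_boxes, gt_boxes = Tensor(np.zeros((0, 4))), np.zeros((0, 4))

        # affinity branch: embeddings at gt cells vs previous-frame memory
        emb_grid = (out0.d_a * 0.5 + out0.d_m * 0.5).reshape(hs, ws, -1)
        if prev_ids and not flip:
            U = emb_grid[iy, ix]
            V = Tensor(0.5 * (t_a + t_m))
            scores = model.affinity_net(U, V)
            labels = np.array([[1.0 if ci == pi else 0.0 for pi in prev_ids]
                               for ci in cur_ids])
        else:
            scores, labels = Tensor(np.zeros((0, 0))), np.zeros((0, 0))

        from .autodiff import concat as cat2
        heat_both = cat2([det_a.heatmap.reshape(-1), det_m.heatmap.reshape(-1)])
        heat_t2 = np.concatenate([heat_t.ravel(), heat_t.ravel()])
        boxes_both = cat2([boxes_at, boxes_at_m], axis=0)
        offs_both = cat2([offs_at, offs_at_m], axis=0)
        bundle = compute_losses(
            heat_both, boxes_both, offs_both, heat_t2,
            np.concatenate([box_t, box_t]), np.concatenate([off_t, off_t]),
            disp_boxes, gt_boxes, scores, labels,
            cfg.head.focal_alpha, cfg.head.focal_beta)
        opt.zero_grad()
        bundle.total.backward()
        opt.lr = cosine_warmup_lr(step_i, cfg.train.lr, warmup, steps)
        opt.step()
        losses.append(float(bundle.total.data))
        if log_every and step_i % log_every == 0:
            log.info("step %d: loss %.4f", step_i, losses[-1])

        # refresh teacher-forced memory (detached)
        if not flip:
            refs = np.array([((r[1] + r[3] / 2) / frame.shape[1],
                              (r[2] + r[4] / 2) / frame.shape[0])
                             for r in seq.records[k]])
            with no_grad():
                mem_q_a = np.array([id_mem.get(i, (np.zeros(h), np.zeros(h)))[0]
                                    for i in cur_ids])
                mem_q_m = np.array([id_mem.get(i, (np.zeros(h), np.zeros(h)))[1]
                                    for i in cur_ids])
                dec_a = model.decode_memory(fused, mem_q_a, refs, "appearance").data
                dec_m = model.decode_memory(fused, mem_q_m, refs, "motion").data
            mom = cfg.mhgn.mem_momentum
            for idx, i in enumerate(cur_ids):
                old = id_mem.get(i, (np.zeros(h), np.zeros(h)))
                id_mem[i] = (mom * old[0] + (1 - mom) * dec_a[idx],
                             mom * old[1] + (1 - mom) * dec_m[idx])
            for (tid, left, top, w, hh) in seq.records[k]:
                id_center[tid] = (left + w / 2, top + hh / 2)
                id_box[tid] = (left, top, w, hh)
    return model, losses


def stack_channels(grid_tensor: Tensor, iy: np.ndarray, ix: np.ndarray) -> Tensor:
    """Gather (C, H, W) channels at cells -> (n, C)."""
    return grid_tensor[:, iy, ix].T


# ----------------------------------------------------------------------
# checkpointing
# ----------------------------------------------------------------------

def save_checkpoint(model: HGTModel, path) -> None:
    np.savez(path, **model.state_dict())


def load_checkpoint(model: HGTModel, path) -> HGTModel:
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
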