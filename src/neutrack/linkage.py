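"""Trajectory linkage over score-matrix chains.

Four linkers operate on the same substrate, a chain of per-adjacent-frame
score matrices:

* ``link_greedy_delta`` — frame-by-frame argmax linkage; each detection can
  be passed by at most one trajectory.
* ``link_hungarian`` — per frame pair a maximum-score one-to-one
  assignment, with a score threshold as end condition.
* ``link_viterbi_basic`` — per seed, dynamic programming maximising the
  product of step scores over the whole chain (routing forward, retrieval
  backward), with an optional truncation post-processing for collapsed
  tracks.
* ``link_viterbi_extended`` — the full algorithm: routing consults an
  occupancy map; an occupied detection is connectable only when the
  routing track's accumulated score clears a geometrically discounted
  merge threshold (Condition 1) or every occupant has fallen below it
  (Condition 2); tracks whose best transition drops below a truncation
  floor are declared disappeared; uncovered detections seed new
  trajectories; a strictly better later track can evict and re-route a
  weak occupant (reroute).

Accumulated scores are products of step scores, handled in log space.
Ties in the dynamic-programming argmax are broken toward the lower cell
label, for reproducibility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .scoring import ScoreMatrix

__all__ = [
    "LinkageParams",
    "Trajectory",
    "TrackingResult",
    "discount_threshold",
    "link_greedy_delta",
    "link_hungarian",
    "link_viterbi_basic",
    "link_viterbi_extended",
    "truncate_collapsed",
    "link",
    "LINKERS",
]

# trajectory end states
ACTIVE = "active"
ENDED_LAST_FRAME = "ended_last_frame"
ENDED_ZERO_SCORES = "ended_zero_scores"
ENDED_NO_AVAILABLE_CELL = "ended_no_available_cell"
TRUNCATED_DISAPPEARED = "truncated_disappeared"

_NEG_INF = float("-inf")


@dataclass(frozen=True)
class LinkageParams:
    """Thresholds of the linkage stage.

    T_truncated: score floor below which a track is declared disappeared;
    T_merge: base threshold of the merge conditions, discounted per layer;
    end_threshold: assignment cut-off (Hungarian linker only);
    reroute_factor: >= 1, how much better a later track must be to evict
    an occupant.
    """

    T_truncated: float = 0.001
    T_merge: float = 0.875
    end_threshold: float = 0.001
    reroute_factor: float = 1.0

    def __post_init__(self) -> None:
        for name in ("T_truncated", "T_merge", "end_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.reroute_factor < 1.0:
            raise ValueError("reroute_factor must be >= 1")


def discount_threshold(T_merge: float, frame_number: int) -> float:
    """Geometric discount of the merge threshold along a track.

    Returns ``T_merge ** (frame_number - 1)`` where ``frame_number`` counts
    from the track's first frame (1 at birth).  Accumulated track scores
    are products of per-step probabilities and decay geometrically, so the
    comparison threshold must decay with them.
    """
    if frame_number < 1:
        raise ValueError("frame_number must be >= 1")
    return float(T_merge) ** (frame_number - 1)


@dataclass(eq=False)
class Trajectory:
    """An ordered chain of (frame, cell_label) nodes with step scores."""

    track_id: int
    nodes: list[tuple[int, int]]
    step_scores: list[float] = field(default_factory=list)
    status: str = ACTIVE

    @property
    def accumulated_score(self) -> float:
        out = 1.0
        for s in self.step_scores:
            out *= s
        return out

    def acc_upto(self, n_nodes: int) -> float:
        """Accumulated product over the first ``n_nodes`` nodes."""
        out = 1.0
        for s in self.step_scores[:max(0, n_nodes - 1)]:
            out *= s
        return out

    @property
    def frames(self) -> list[int]:
        return [f for f, _ in self.nodes]

    def __len__(self) -> int:
        return len(self.nodes)


@dataclass
class TrackingResult:
    trajectories: list[Trajectory]
    params: LinkageParams
    method: str
    merge_log: list[dict] = field(default_factory=list)

    def occupancy(self) -> dict[tuple[int, int], set[int]]:
        occ: dict[tuple[int, int], set[int]] = {}
        for tr in self.trajectories:
            for node in tr.nodes:
                occ.setdefault(node, set()).add(tr.track_id)
        return occ


# ---------------------------------------------------------------------------
# chain helpers
# ---------------------------------------------------------------------------

class _Chain:
    """Index/label bookkeeping over a consistent ScoreMatrix chain."""

    def __init__(self, matrices: list[ScoreMatrix]):
        if not matrices:
            raise ValueError("empty matrix chain")
        self.matrices = matrices
        self.n_frames = len(matrices) + 1
        self.labels: list[list[int]] = [list(matrices[0].row_labels)]
        for m in matrices:
            self.labels.append(list(m.col_labels))
        for t in range(1, len(matrices)):
            if matrices[t].row_labels != matrices[t - 1].col_labels:
                raise ValueError("matrix chain labels are inconsistent")
        self.row_idx = [
            {lab: i for i, lab in enumerate(m.row_labels)} for m in matrices]
        self.col_idx = [
            {lab: j for j, lab in enumerate(m.col_labels)} for m in matrices]

    def score(self, t: int, lab_from: int, lab_to: int) -> float:
        m = self.matrices[t]
        return float(m.scores[self.row_idx[t][lab_from],
                              self.col_idx[t][lab_to]])

    def row(self, t: int, lab_from: int) -> np.ndarray:
        return self.matrices[t].scores[self.row_idx[t][lab_from]]


def _diagnose_end(chain: _Chain, frame: int, label: int,
                  floor: float) -> str:
    """Why did a trajectory stop at (frame, label)?"""
    if frame == chain.n_frames - 1:
        return ENDED_LAST_FRAME
    row = chain.row(frame, label)
    if row.size == 0 or float(row.max()) <= 0.0:
        return ENDED_ZERO_SCORES
    if float(row.max()) < floor:
        return TRUNCATED_DISAPPEARED
    return ENDED_NO_AVAILABLE_CELL


# ---------------------------------------------------------------------------
# greedy (DeLTA-style) linkage
# ---------------------------------------------------------------------------

def link_greedy_delta(matrices: list[ScoreMatrix],
                      params: LinkageParams = LinkageParams()
                      ) -> TrackingResult:
    """Frame-by-frame argmax linkage; each detection passed at most once.

    Each active track links to the next-frame cell with the highest score
    in its row.  When two tracks contend for the same best cell the
    earlier track (lower row order) takes it and the other ends; the
    orphaned detection later seeds a new trajectory.  Detections at any
    frame not claimed by a track start new trajectories.
    """
    chain = _Chain(matrices)
    trajectories: list[Trajectory] = []
    next_id = 1
    active: list[Trajectory] = []
    for lab in chain.labels[0]:
        tr = Trajectory(next_id, [(0, lab)])
        next_id += 1
        trajectories.append(tr)
        active.append(tr)
    for t in range(chain.n_frames - 1):
        claimed: set[int] = set()
        still = []
        for tr in active:
            lab = tr.nodes[-1][1]
            row = chain.row(t, lab)
            if row.size == 0 or float(row.max()) <= 0.0:
                tr.status = ENDED_ZERO_SCORES
                continue
            j = int(np.argmax(row))  # ties -> first (lowest) column
            target = chain.labels[t + 1][j]
            if target in claimed:
                tr.status = ENDED_NO_AVAILABLE_CELL
                continue
            claimed.add(target)
            tr.nodes.append((t + 1, target))
            tr.step_scores.append(float(row[j]))
            still.append(tr)
        for lab in chain.labels[t + 1]:
            if lab not in claimed:
                tr = Trajectory(next_id, [(t + 1, lab)])
                next_id += 1
                trajectories.append(tr)
                still.append(tr)
        active = still
    for tr in active:
        tr.status = ENDED_LAST_FRAME
    return TrackingResult(trajectories, params, "greedy")


# ---------------------------------------------------------------------------
# Hungarian linkage
# ---------------------------------------------------------------------------

def link_hungarian(matrices: list[ScoreMatrix],
                   params: LinkageParams = LinkageParams()
                   ) -> TrackingResult:
    """Per frame pair, a maximum-score one-to-one assignment.

    Assignments with zero score are cut as dead ends; assignments scoring
    below ``params.end_threshold`` end the track as disappeared.
    Unassigned next-frame cells start new trajectories.
    """
    chain = _Chain(matrices)
    trajectories: list[Trajectory] = []
    next_id = 1
    track_at: dict[int, Trajectory] = {}
    for lab in chain.labels[0]:
        tr = Trajectory(next_id, [(0, lab)])
        next_id += 1
        trajectories.append(tr)
        track_at[lab] = tr
    for t in range(chain.n_frames - 1):
        scores = matrices[t].scores
        nxt: dict[int, Trajectory] = {}
        assigned_cols: set[int] = set()
        if scores.size:
            rows, cols = linear_sum_assignment(-scores)
            for i, j in zip(rows, cols):
                lab_from = chain.labels[t][i]
                lab_to = chain.labels[t + 1][j]
                s = float(scores[i, j])
                tr = track_at.get(lab_from)
                if tr is None:
                    continue
                if s <= 0.0:
                    tr.status = ENDED_ZERO_SCORES
                elif s < params.end_threshold:
                    tr.status = TRUNCATED_DISAPPEARED
                else:
                    tr.nodes.append((t + 1, lab_to))
                    tr.step_scores.append(s)
                    nxt[lab_to] = tr
                    assigned_cols.add(j)
        for tr in track_at.values():
            if tr.status == ACTIVE and tr.nodes[-1][0] == t:
                tr.status = ENDED_NO_AVAILABLE_CELL
        for j, lab in enumerate(chain.labels[t + 1]):
            if j not in assigned_cols:
                tr = Trajectory(next_id, [(t + 1, lab)])
                next_id += 1
                trajectories.append(tr)
                nxt[lab] = tr
        track_at = nxt
    for tr in track_at.values():
        if tr.status == ACTIVE:
            tr.status = ENDED_LAST_FRAME
    return TrackingResult(trajectories, params, "hungarian")


# ---------------------------------------------------------------------------
# Viterbi routing engine (shared by basic and extended)
# ---------------------------------------------------------------------------

def _route(chain: _Chain, seed_frame: int, seed_label: int,
           params: LinkageParams, *,
           start_logv: float = 0.0,
           occupancy: dict | None = None,
           acc_table: dict | None = None,
           track_birth: dict | None = None,
           self_id: int | None = None,
           floor: float = 0.0,
           birth_frame: int | None = None):
    """Forward DP + backward retrieval for one trajectory.

    Returns (nodes, step_scores, cond2_nodes, status).  ``occupancy`` maps
    node -> set of track ids; when given, transitions into occupied nodes
    must satisfy the discounted merge conditions.  ``floor`` disallows
    steps scoring below it (the truncation threshold).  ``birth_frame``
    anchors the layer count of the discount (defaults to ``seed_frame``;
    a re-routed continuation keeps its original birth).
    """
    if birth_frame is None:
        birth_frame = seed_frame
    use_occ = occupancy is not None
    # values[t] maps label -> (logv, parent_label, step_score, used_cond2)
    values: list[dict] = [dict() for _ in range(chain.n_frames)]
    values[seed_frame][seed_label] = (start_logv, None, None, False)
    last_layer = seed_frame
    for t in range(seed_frame, chain.n_frames - 1):
        cur = values[t]
        if not cur:
            break
        nxt = values[t + 1]
        layer_number = t + 1 - birth_frame + 1  # 1-based along the track
        disc = discount_threshold(params.T_merge, layer_number) if use_occ \
            else 0.0
        for lab_to in chain.labels[t + 1]:
            best = None
            for lab_from, (logv, *_rest) in cur.items():
                s = chain.score(t, lab_from, lab_to)
                if s <= 0.0 or s < floor:
                    continue
                cand = logv + math.log(s)
                used_cond2 = False
                if use_occ:
                    occ = occupancy.get((t + 1, lab_to))
                    occ = {o for o in occ if o != self_id} if occ else None
                    if occ:
                        cond1 = math.exp(cand) >= disc - 1e-12
                        cond2 = all(
                            acc_table.get((o, (t + 1, lab_to)), 1.0)
                            < discount_threshold(
                                params.T_merge,
                                t + 1 - track_birth.get(o, 0) + 1) - 1e-12
                            for o in occ)
                        if not (cond1 or cond2):
                            continue
                        used_cond2 = not cond1
                key = (cand, -lab_from)  # ties -> lower predecessor label
                if best is None or key > best[0]:
                    best = (key, lab_from, s, used_cond2)
            if best is not None:
                nxt[lab_to] = (best[0][0], best[1], best[2], best[3])
        if nxt:
            last_layer = t + 1
        else:
            break
    # retrieval: argmax at the furthest reached layer, ties -> lower label
    terminal = min(values[last_layer],
                   key=lambda lab: (-values[last_layer][lab][0], lab))
    nodes: list[tuple[int, int]] = []
    steps: list[float] = []
    cond2_nodes: list[tuple[int, int]] = []
    lab = terminal
    for t in range(last_layer, seed_frame, -1):
        logv, parent, s, used_cond2 = values[t][lab]
        nodes.append((t, lab))
        steps.append(s)
        if used_cond2:
            cond2_nodes.append((t, lab))
        lab = parent
    nodes.append((seed_frame, lab))
    nodes.reverse()
    steps.reverse()
    status = _diagnose_end(chain, last_layer, terminal, floor)
    return nodes, steps, cond2_nodes, status


# ---------------------------------------------------------------------------
# basic Viterbi
# ---------------------------------------------------------------------------

def truncate_collapsed(result: TrackingResult) -> TrackingResult:
    """Post-processing for collapsed tracks.

    Once a trajectory has entered a node shared with another trajectory,
    it is truncated at the first step whose score is lower than the
    preceding step's score.
    """
    occ = result.occupancy()
    for tr in result.trajectories:
        shared_from = None
        for k, node in enumerate(tr.nodes):
            if len(occ[node]) >= 2:
                shared_from = k
                break
        if shared_from is None:
            continue
        for s in range(max(shared_from, 1), len(tr.step_scores)):
            if tr.step_scores[s] < tr.step_scores[s - 1]:
                tr.nodes = tr.nodes[:s + 1]
                tr.step_scores = tr.step_scores[:s]
                break
    return result


def link_viterbi_basic(matrices: list[ScoreMatrix],
                       params: LinkageParams = LinkageParams(),
                       truncate: bool = True) -> TrackingResult:
    """Independent per-seed dynamic programming over the whole chain.

    Every first-frame cell (and every later detection left uncovered) is
    routed to the path maximising the product of its step scores, with no
    occupancy constraints — after merges, tracks may collapse onto shared
    nodes.  ``truncate`` applies :func:`truncate_collapsed` afterwards.
    """
    chain = _Chain(matrices)
    trajectories: list[Trajectory] = []
    covered: set[tuple[int, int]] = set()
    next_id = 1
    seeds = [(0, lab) for lab in chain.labels[0]]
    for f in range(1, chain.n_frames):
        seeds.extend((f, lab) for lab in chain.labels[f])
    for f, lab in seeds:
        if (f, lab) in covered:
            continue
        nodes, steps, _, status = _route(chain, f, lab, params)
        tr = Trajectory(next_id, nodes, steps, status)
        next_id += 1
        trajectories.append(tr)
        covered.update(nodes)
    result = TrackingResult(trajectories, params, "viterbi")
    if not truncate:
        return result
    truncate_collapsed(result)
    # truncation may orphan detections; re-seed them so every detection
    # is still covered by some trajectory
    covered = set(result.occupancy())
    for f, lab in seeds:
        if (f, lab) in covered:
            continue
        nodes, steps, _, status = _route(chain, f, lab, params)
        tr = Trajectory(next_id, nodes, steps, status)
        next_id += 1
        result.trajectories.append(tr)
        covered.update(nodes)
    return result


# ---------------------------------------------------------------------------
# extended Viterbi
# ---------------------------------------------------------------------------

def link_viterbi_extended(matrices: list[ScoreMatrix],
                          params: LinkageParams = LinkageParams()
                          ) -> TrackingResult:
    """Viterbi routing with occupancy, merge/split, and rerouting.

    Tracks are routed sequentially (first-frame cells in ascending label
    order, then appearing cells in frame order).  A transition into a node
    already occupied by other trajectories is allowed only under the
    discounted merge conditions; trajectories satisfying them share nodes
    (a merge) and separate again at the first layer where the conditions
    fail or their own optima diverge (a split).  A track whose best
    remaining transition scores below ``T_truncated`` is terminated as
    disappeared.  A later track entering via Condition 2 with a strictly
    better accumulated score (by ``reroute_factor``) evicts the weak
    occupant, which is re-routed from the contested layer (single sweep).
    """
    chain = _Chain(matrices)
    occupancy: dict[tuple[int, int], set[int]] = {}
    acc_table: dict[tuple[int, tuple[int, int]], float] = {}
    track_birth: dict[int, int] = {}
    by_id: dict[int, Trajectory] = {}
    merge_log: list[dict] = []
    next_id = 1

    def commit(tr: Trajectory) -> None:
        for k, node in enumerate(tr.nodes):
            occupancy.setdefault(node, set()).add(tr.track_id)
            acc_table[(tr.track_id, node)] = tr.acc_upto(k + 1)

    def route_new(frame: int, label: int) -> Trajectory:
        nonlocal next_id
        tid = next_id
        next_id += 1
        track_birth[tid] = frame
        nodes, steps, cond2_nodes, status = _route(
            chain, frame, label, params,
            occupancy=occupancy, acc_table=acc_table,
            track_birth=track_birth, self_id=tid,
            floor=params.T_truncated)
        tr = Trajectory(tid, nodes, steps, status)
        by_id[tid] = tr
        # log merges for auditability
        for node in nodes:
            occ = occupancy.get(node)
            if occ:
                cond = "cond2" if node in cond2_nodes else "cond1"
                merge_log.append({"node": node, "track_id": tid,
                                  "condition": cond,
                                  "occupants": sorted(occ)})
        commit(tr)
        _reroute_pass(tr, cond2_nodes)
        return tr

    def _reroute_pass(tr: Trajectory, cond2_nodes) -> None:
        """Evict strictly weaker occupants at contested (Condition-2) nodes."""
        for node in cond2_nodes:
            my_acc = acc_table[(tr.track_id, node)]
            for oid in sorted(occupancy.get(node, set()) - {tr.track_id}):
                occ_acc = acc_table.get((oid, node), 1.0)
                if my_acc > occ_acc * params.reroute_factor:
                    _reset_from(by_id[oid], node)

    def _reset_from(victim: Trajectory, node: tuple[int, int]) -> None:
        """Truncate ``victim`` before ``node`` and re-route its tail."""
        try:
            k = victim.nodes.index(node)
        except ValueError:
            return
        if k == 0:
            return  # never evict a seed node
        for n in victim.nodes[k:]:
            occupancy.get(n, set()).discard(victim.track_id)
            acc_table.pop((victim.track_id, n), None)
        victim.nodes = victim.nodes[:k]
        victim.step_scores = victim.step_scores[:k - 1]
        f0, lab0 = victim.nodes[-1]
        logv = math.log(victim.accumulated_score) \
            if victim.accumulated_score > 0 else _NEG_INF
        nodes, steps, _, status = _route(
            chain, f0, lab0, params, start_logv=logv,
            occupancy=occupancy, acc_table=acc_table,
            track_birth=track_birth, self_id=victim.track_id,
            floor=params.T_truncated,
            birth_frame=track_birth[victim.track_id])
        victim.nodes = victim.nodes[:-1] + nodes
        victim.step_scores = victim.step_scores + steps
        victim.status = status
        for k2 in range(len(victim.nodes)):
            n = victim.nodes[k2]
            occupancy.setdefault(n, set()).add(victim.track_id)
            acc_table[(victim.track_id, n)] = victim.acc_upto(k2 + 1)

    # primary routing: first-frame cells in ascending label order
    for lab in sorted(chain.labels[0]):
        route_new(0, lab)
    # appearance pass: uncovered detections seed new trajectories
    for f in range(1, chain.n_frames):
        for lab in sorted(chain.labels[f]):
            if (f, lab) not in occupancy:
                route_new(f, lab)

    trajectories = [by_id[t] for t in sorted(by_id)]
    return TrackingResult(trajectories, params, "viterbi-ext", merge_log)


LINKERS = {
    "greedy": link_greedy_delta,
    "hungarian": link_hungarian,
    "viterbi": link_viterbi_basic,
    "viterbi-ext": link_viterbi_extended,
}


def link(matrices: list[ScoreMatrix], method: str = "viterbi-ext",
         params: LinkageParams = LinkageParams()) -> TrackingResult:
    """Dispatch to one of the four linkers by name."""
    try:
        linker = LINKERS[method]
    except KeyError:
        raise ValueError(f"unknown linkage method {method!r}; "
                         f"choose from {sorted(LINKERS)}") from None
    return linker(matrices, params)
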