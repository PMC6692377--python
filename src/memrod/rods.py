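"""Construction and embedding of crescent protein rods.

A rod is ten membrane particles on a circular arc of curvature ``c_rod``
(chord spacing = rest bond length, ``r_rod = 10 sigma`` end to end when
straight) whose orientations are the outward arc normals.  Hook particles
are placed between the first and second particles of both rod ends at one
bond length from both anchors, displaced laterally (in the local membrane
plane, perpendicular to the backbone).  For a chiral rod the two hooks sit
on right-handed positions (opposite lateral sides when expressed in the
space frame); for an achiral hooked rod both sit on the same side, which
makes the fragment superimposable on its mirror image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (KIND_BACKBONE, KIND_HOOK, KIND_MEMBRANE, ACHIRAL_PLAIN,
                   ACHIRAL_HOOKED, CHIRAL, ParticleState, RodSpec,
                   SimulationBox, minimum_image)
from .potentials import _arc_chain

__all__ = ["RodPlacement", "build_rod", "detect_handedness", "embed_rods",
           "mirror_state", "hook_positions"]

OVERLAP_MIN = 0.8   # insertion hard-core threshold, in sigma


@dataclass
class RodPlacement:
    rod_id: int
    anchor: np.ndarray          # position of the first backbone particle
    direction: np.ndarray       # initial in-plane walk direction
    handedness: str


def hook_positions(back_pos: np.ndarray, back_u: np.ndarray, spec: RodSpec):
    """Hook particle positions for a backbone fragment (ordered by segment).

    Each hook forms an equilateral triangle with its two anchor particles.
    Its offset from the anchor midpoint combines a lateral component along
    ``t_in x u`` (``t_in`` = bond direction taken from the rod end inward)
    and an elevation along ``u`` (the protein protrudes on the membrane's
    outer side, which also leaves room to insert the hook into a dense
    sheet).  Lateral signs (+, +) give the right-handed chiral rod, (+, -)
    the achiral hooked rod; the elevation carries no handedness.
    """
    d = spec.bond_length * spec.hook_offset_factor
    psi = np.deg2rad(spec.hook_elevation_deg)
    out = []
    signs = (1.0, 1.0) if spec.chirality == CHIRAL else (1.0, -1.0)
    ends = [(0, 1), (len(back_pos) - 1, len(back_pos) - 2)]
    for (e, inner), s in zip(ends, signs):
        t_in = back_pos[inner] - back_pos[e]
        t_in /= np.linalg.norm(t_in)
        u_mid = back_u[e] + back_u[inner]
        u_mid /= np.linalg.norm(u_mid)
        b = np.cross(t_in, u_mid)
        nb = np.linalg.norm(b)
        if nb < 1e-10:
            raise ValueError("degenerate rod geometry: u parallel to backbone")
        b /= nb
        mid = 0.5 * (back_pos[e] + back_pos[inner])
        offset = (np.sqrt(3.0) / 2.0) * d * (np.cos(psi) * s * b
                                             + np.sin(psi) * u_mid)
        out.append(mid + offset)
    return np.asarray(out)


def build_rod(spec: RodSpec, rod_id: int = 0) -> ParticleState:
    """A single rod fragment at the origin, lying in the z = 0 plane."""
    pos, u = _arc_chain(spec.n_backbone, spec.bond_length, spec.c_rod)
    kind = np.full(spec.n_backbone, KIND_BACKBONE, dtype=np.int8)
    seg = np.arange(spec.n_backbone, dtype=np.int16)
    if spec.has_hooks:
        hp = hook_positions(pos, u, spec)
        hu = np.tile([0.0, 0.0, 1.0], (2, 1))
        pos = np.vstack([pos, hp])
        u = np.vstack([u, hu])
        kind = np.concatenate([kind, np.full(2, KIND_HOOK, dtype=np.int8)])
        seg = np.concatenate([seg, np.full(2, -1, dtype=np.int16)])
    n = len(pos)
    return ParticleState(pos, u, kind,
                         np.full(n, rod_id, dtype=np.int32), seg)


def detect_handedness(fragment: ParticleState, rod_id: int = 0,
                      tol: float = 1e-6) -> str:
    """Handedness from the triple product (outward tangent, hook offset, u).

    The score of each hook is ``t_out . (h x u)`` with ``t_out`` the bond
    direction pointing out of the rod end, ``h`` the hook offset from the
    anchor midpoint and ``u`` the mean anchor orientation.  The built chiral
    rod scores positive at both ends (right); its mirror scores negative
    (left); the achiral hooked rod sums to zero.
    """
    back = fragment.rod_backbone_indices(rod_id)
    hooks = np.where((fragment.rod_id == rod_id)
                     & (fragment.kind == KIND_HOOK))[0]
    if len(hooks) == 0:
        return "achiral"
    score = 0.0
    norm = 0.0
    for h in hooks:
        d0 = np.linalg.norm(fragment.pos[h] - fragment.pos[back[0]])
        d9 = np.linalg.norm(fragment.pos[h] - fragment.pos[back[-1]])
        e, inner = (back[0], back[1]) if d0 < d9 else (back[-1], back[-2])
        t_out = fragment.pos[e] - fragment.pos[inner]
        tn = np.linalg.norm(t_out)
        if tn < 1e-10:
            raise ValueError("degenerate rod geometry: coincident anchors")
        t_out /= tn
        u_mid = fragment.orient[e] + fragment.orient[inner]
        u_mid /= np.linalg.norm(u_mid)
        hvec = fragment.pos[h] - 0.5 * (fragment.pos[e] + fragment.pos[inner])
        hvec /= np.linalg.norm(hvec)
        score += float(t_out @ np.cross(hvec, u_mid))
        norm += 1.0
    score /= norm
    if score > tol:
        return "right"
    if score < -tol:
        return "left"
    return "achiral"


def mirror_state(state: ParticleState, axis: int = 1) -> ParticleState:
    """Reflect positions and orientations through the plane x_axis = 0."""
    m = state.copy()
    m.pos[:, axis] *= -1.0
    m.orient[:, axis] *= -1.0
    return m


def embed_rod_at(membrane: ParticleState, spec: RodSpec,
                 box: SimulationBox, point, direction) -> ParticleState:
    """Convert one membrane chain into a rod at a prescribed place.

    Starts from the free membrane particle nearest ``point`` and walks in
    ``direction`` (projected into the local tangent plane).  Deterministic;
    raises if the walk cannot find particles near its targets.
    """
    st = membrane.copy()
    free = np.where(st.kind == KIND_MEMBRANE)[0]
    disp = minimum_image(st.pos[free] - np.asarray(point, dtype=float), box)
    i0 = int(free[np.argmin(np.linalg.norm(disp, axis=1))])
    t = np.asarray(direction, dtype=float)
    t -= (t @ st.orient[i0]) * st.orient[i0]
    t /= np.linalg.norm(t)
    d = spec.bond_length
    chain = [i0]
    used = {i0}
    for _ in range(spec.n_backbone - 1):
        target = st.pos[chain[-1]] + d * t
        cand = np.where(st.kind == KIND_MEMBRANE)[0]
        cand = cand[~np.isin(cand, list(used))]
        disp = minimum_image(st.pos[cand] - target, box)
        dist = np.linalg.norm(disp, axis=1)
        k = int(np.argmin(dist))
        if dist[k] > 0.9:
            raise RuntimeError("no membrane particle near the walk target")
        nxt = int(cand[k])
        step = minimum_image(st.pos[nxt] - st.pos[chain[-1]], box)
        t = step / np.linalg.norm(step)
        chain.append(nxt)
        used.add(nxt)
    chain = np.asarray(chain)
    back_pos = st.pos[chain].copy()
    for s in range(1, len(back_pos)):
        step = np.asarray(minimum_image(back_pos[s] - back_pos[s - 1], box))
        back_pos[s] = back_pos[s - 1] + step / np.linalg.norm(step) * d
    rid = st.n_rods
    st.pos[chain] = back_pos
    st.kind[chain] = KIND_BACKBONE
    st.rod_id[chain] = rid
    st.seg[chain] = np.arange(spec.n_backbone, dtype=np.int16)
    if spec.has_hooks:
        hp = hook_positions(back_pos, st.orient[chain], spec)
        hook_u = st.orient[chain[[0, -1]]].copy()
        st = ParticleState(
            np.vstack([st.pos, hp]),
            np.vstack([st.orient, hook_u]),
            np.concatenate([st.kind, np.full(2, KIND_HOOK, dtype=np.int8)]),
            np.concatenate([st.rod_id, np.full(2, rid, dtype=np.int32)]),
            np.concatenate([st.seg, np.full(2, -1, dtype=np.int16)]))
    return st


def embed_rods(membrane: ParticleState, n_rods: int, spec: RodSpec,
               box: SimulationBox, seed: int = 0,
               max_tries: int = 200) -> ParticleState:
    """Convert membrane particles into ``n_rods`` rod backbones.

    Each rod is grown as a walk over existing free membrane particles from a
    random start in a random in-plane direction, which conserves the total
    non-hook particle count (so ``phi_rod = 10 n_rods / N``).  Hook
    particles are inserted as additional particles; a placement is rejected
    and retried if any inserted hook comes closer than 0.8 sigma to an
    existing particle.  Deterministic under a fixed seed.
    """
    if n_rods == 0:
        return membrane.copy()
    rng = np.random.default_rng(seed)
    st = membrane.copy()
    d = spec.bond_length
    next_rod = st.n_rods
    placed = 0
    tries = 0
    while placed < n_rods:
        tries += 1
        if tries > max_tries * n_rods:
            raise RuntimeError(
                f"rod insertion failed after {tries} attempts "
                f"({placed}/{n_rods} placed)")
        free = np.where(st.kind == KIND_MEMBRANE)[0]
        if len(free) < spec.n_backbone:
            raise RuntimeError("not enough free membrane particles")
        i0 = int(rng.choice(free))
        u0 = st.orient[i0]
        t = rng.normal(size=3)
        t -= (t @ u0) * u0
        tn = np.linalg.norm(t)
        if tn < 1e-8:
            continue
        t /= tn
        chain = [i0]
        used = {i0}
        ok = True
        for _ in range(spec.n_backbone - 1):
            target = st.pos[chain[-1]] + d * t
            cand = np.where(st.kind == KIND_MEMBRANE)[0]
            cand = cand[~np.isin(cand, list(used))]
            disp = minimum_image(st.pos[cand] - target, box)
            dist = np.linalg.norm(disp, axis=1)
            k = int(np.argmin(dist))
            if dist[k] > 0.9:
                ok = False
                break
            nxt = int(cand[k])
            step = minimum_image(st.pos[nxt] - st.pos[chain[-1]], box)
            t = step / np.linalg.norm(step)
            chain.append(nxt)
            used.add(nxt)
        if not ok:
            continue
        chain = np.asarray(chain)
        # snap the selected chain to rest bond lengths (the walk picks
        # particles up to ~0.9 sigma off target; stiff bonds would other-
        # wise inject a large energy spike at t = 0); unwrapped coordinates
        back_pos = st.pos[chain].copy()
        for s in range(1, len(back_pos)):
            step = np.asarray(minimum_image(back_pos[s] - back_pos[s - 1],
                                            box))
            back_pos[s] = back_pos[s - 1] + step / np.linalg.norm(step) * d
        # reject if the snapped chain crowds other particles
        mask_other = np.ones(st.n, dtype=bool)
        mask_other[chain] = False
        d_min = np.inf
        for p in back_pos:
            disp = minimum_image(st.pos[mask_other] - p, box)
            d_min = min(d_min, float(np.linalg.norm(disp, axis=1).min()))
        if d_min < 0.7:
            continue
        # hooks from the local geometry of the snapped chain
        if spec.has_hooks:
            try:
                hp = hook_positions(back_pos, st.orient[chain], spec)
            except ValueError:
                continue
            d_min = np.inf
            for p in hp:
                disp = minimum_image(st.pos[mask_other] - p, box)
                d_min = min(d_min, float(np.linalg.norm(disp, axis=1).min()))
                dd = np.sort(np.linalg.norm(back_pos - p, axis=1))
                d_min = min(d_min, float(dd[2]))   # beyond the two anchors
            if d_min < OVERLAP_MIN:
                continue
        st.pos[chain] = back_pos
        st.kind[chain] = KIND_BACKBONE
        st.rod_id[chain] = next_rod
        st.seg[chain] = np.arange(spec.n_backbone, dtype=np.int16)
        if spec.has_hooks:
            hook_u = st.orient[chain[[0, -1]]].copy()
            st = ParticleState(
                np.vstack([st.pos, hp]),
                np.vstack([st.orient, hook_u]),
                np.concatenate([st.kind, np.full(2, KIND_HOOK, dtype=np.int8)]),
                np.concatenate([st.rod_id, np.full(2, next_rod, dtype=np.int32)]),
                np.concatenate([st.seg, np.full(2, -1, dtype=np.int16)]))
        next_rod += 1
        placed += 1
    return st
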