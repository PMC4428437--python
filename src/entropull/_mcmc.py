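"""Numba kernel for Metropolis sampling of the chaperone-bound complex.

State layout (all coordinates in Angstrom, energies in k_BT):

* ``sub``      -- (n, 3) substrate beads; row i is residue i+1.  Rows 0-6
                  (the clamped heptapeptide) belong to the SBD rigid unit;
                  row n-1 is pinned at the origin on the wall; rows
                  7 .. n-2 are free.
* ``sbd_ref``, ``clamp_ref`` -- reference coordinates of the SBD rigid unit
                  (interaction subset of the domain plus the clamp); world
                  coordinates are ``ref @ R_s.T + t_s``.
* ``nbd_ref``  -- reference NBD coordinates, pose (R_n, t_n).
* ``lnk``      -- (nl, 3) flexible linker beads, bonded
                  NBD-anchor - l0 - ... - l(nl-1) - SBD-anchor.

Move set per sweep: one Gaussian displacement per free substrate bead, one
proposal per linker bead, two rigid SBD moves (rotation about the clamp
centroid + translation), two rigid NBD moves (rotation about its anchor +
translation) and two pivot moves (rotation of everything on the clamp side
of a randomly chosen substrate bead, chaperone included).  Proposals are
symmetric, accepted by the Metropolis rule on the energy difference; any
proposal placing a substrate bead centre below z = 0 is rejected outright
(hard wall).  The wall is transparent to chaperone beads; the per-frame
indicator records whether all chaperone/linker bead centres have z >= 0.

Pair energies for rigid moves are evaluated with the inverse-transform
trick: a rigid proposal preserves intra-unit distances, so the energy of
(moved', static) equals the energy of (moved, inverse-transformed static),
which avoids rebuilding the unit's coordinates for rejected proposals.
"""

import numpy as np
from numba import njit

# move-type indices in the acceptance counters
MOVE_SUB, MOVE_PIVOT, MOVE_SBD, MOVE_NBD, MOVE_LNK = 0, 1, 2, 3, 4


@njit(cache=True, inline="always")
def _wca(r2, s2, eps, rc2):
    if r2 >= rc2:
        return 0.0
    sr6 = (s2 / r2) ** 3
    return 4.0 * eps * (sr6 * sr6 - sr6) + eps


@njit(cache=True)
def _e_point_set(px, py, pz, arr, s2, eps, rc2, skip):
    e = 0.0
    for j in range(arr.shape[0]):
        if j == skip:
            continue
        dx = px - arr[j, 0]
        dy = py - arr[j, 1]
        dz = pz - arr[j, 2]
        e += _wca(dx * dx + dy * dy + dz * dz, s2, eps, rc2)
    return e


@njit(cache=True, inline="always")
def _dist(a, b):
    dx = a[0] - b[0]
    dy = a[1] - b[1]
    dz = a[2] - b[2]
    return np.sqrt(dx * dx + dy * dy + dz * dz)


@njit(cache=True)
def _bond(ax, ay, az, bx, by, bz, r0, kb):
    dx = ax - bx
    dy = ay - by
    dz = az - bz
    r = np.sqrt(dx * dx + dy * dy + dz * dz)
    return 0.5 * kb * (r - r0) * (r - r0)


@njit(cache=True)
def _cosser(c, coeffs):
    e = 0.0
    p = 1.0
    for m in range(coeffs.shape[0]):
        e += coeffs[m] * p
        p *= c
    return e


@njit(cache=True)
def _bend(a, b, c, coeffs):
    # angle at b between bond vectors (b-a) and (c-b); straight => cos=1
    if coeffs.shape[0] == 0:
        return 0.0
    ux = b[0] - a[0]
    uy = b[1] - a[1]
    uz = b[2] - a[2]
    vx = c[0] - b[0]
    vy = c[1] - b[1]
    vz = c[2] - b[2]
    nu = np.sqrt(ux * ux + uy * uy + uz * uz)
    nv = np.sqrt(vx * vx + vy * vy + vz * vz)
    if nu < 1e-12 or nv < 1e-12:
        return 0.0
    cc = (ux * vx + uy * vy + uz * vz) / (nu * nv)
    return _cosser(cc, coeffs)


@njit(cache=True)
def _tors(a, b, c, d, coeffs):
    if coeffs.shape[0] == 0:
        return 0.0
    b1x = b[0] - a[0]
    b1y = b[1] - a[1]
    b1z = b[2] - a[2]
    b2x = c[0] - b[0]
    b2y = c[1] - b[1]
    b2z = c[2] - b[2]
    b3x = d[0] - c[0]
    b3y = d[1] - c[1]
    b3z = d[2] - c[2]
    n1x = b1y * b2z - b1z * b2y
    n1y = b1z * b2x - b1x * b2z
    n1z = b1x * b2y - b1y * b2x
    n2x = b2y * b3z - b2z * b3y
    n2y = b2z * b3x - b2x * b3z
    n2z = b2x * b3y - b2y * b3x
    nn = np.sqrt((n1x * n1x + n1y * n1y + n1z * n1z)
                 * (n2x * n2x + n2y * n2y + n2z * n2z))
    if nn < 1e-12:
        return _cosser(1.0, coeffs)
    cc = (n1x * n2x + n1y * n2y + n1z * n2z) / nn
    if cc > 1.0:
        cc = 1.0
    elif cc < -1.0:
        cc = -1.0
    return _cosser(cc, coeffs)


@njit(cache=True)
def _rand_rotation(scale):
    """Small random rotation: random axis, Gaussian angle of std ``scale``."""
    ax = np.random.normal()
    ay = np.random.normal()
    az = np.random.normal()
    nrm = np.sqrt(ax * ax + ay * ay + az * az)
    if nrm < 1e-12:
        ax, ay, az, nrm = 1.0, 0.0, 0.0, 1.0
    ax /= nrm
    ay /= nrm
    az /= nrm
    ang = scale * np.random.normal()
    ca = np.cos(ang)
    sa = np.sin(ang)
    C = 1.0 - ca
    R = np.empty((3, 3))
    R[0, 0] = ca + ax * ax * C
    R[0, 1] = ax * ay * C - az * sa
    R[0, 2] = ax * az * C + ay * sa
    R[1, 0] = ay * ax * C + az * sa
    R[1, 1] = ca + ay * ay * C
    R[1, 2] = ay * az * C - ax * sa
    R[2, 0] = az * ax * C - ay * sa
    R[2, 1] = az * ay * C + ax * sa
    R[2, 2] = ca + az * az * C
    return R


@njit(cache=True)
def _axis_rotation(ux, uy, uz, ang):
    """Rotation by ``ang`` about the given (unit) axis."""
    ca = np.cos(ang)
    sa = np.sin(ang)
    C = 1.0 - ca
    R = np.empty((3, 3))
    R[0, 0] = ca + ux * ux * C
    R[0, 1] = ux * uy * C - uz * sa
    R[0, 2] = ux * uz * C + uy * sa
    R[1, 0] = uy * ux * C + uz * sa
    R[1, 1] = ca + uy * uy * C
    R[1, 2] = uy * uz * C - ux * sa
    R[2, 0] = uz * ux * C - uy * sa
    R[2, 1] = uz * uy * C + ux * sa
    R[2, 2] = ca + uz * uz * C
    return R


@njit(cache=True)
def _orthonormalize(R):
    # Gram-Schmidt re-orthonormalization to stop pose drift
    for i in range(3):
        for j in range(i):
            d = R[i, 0] * R[j, 0] + R[i, 1] * R[j, 1] + R[i, 2] * R[j, 2]
            R[i, 0] -= d * R[j, 0]
            R[i, 1] -= d * R[j, 1]
            R[i, 2] -= d * R[j, 2]
        nrm = np.sqrt(R[i, 0] ** 2 + R[i, 1] ** 2 + R[i, 2] ** 2)
        R[i, 0] /= nrm
        R[i, 1] /= nrm
        R[i, 2] /= nrm


@njit(cache=True)
def _apply_pose(ref, R, t, out):
    for i in range(ref.shape[0]):
        x = ref[i, 0]
        y = ref[i, 1]
        z = ref[i, 2]
        out[i, 0] = R[0, 0] * x + R[0, 1] * y + R[0, 2] * z + t[0]
        out[i, 1] = R[1, 0] * x + R[1, 1] * y + R[1, 2] * z + t[1]
        out[i, 2] = R[2, 0] * x + R[2, 1] * y + R[2, 2] * z + t[2]


@njit(cache=True)
def _inv_transform_point(p, dR, c, dt, out):
    # out = dR^T (p - c - dt) + c
    x = p[0] - c[0] - dt[0]
    y = p[1] - c[1] - dt[1]
    z = p[2] - c[2] - dt[2]
    out[0] = dR[0, 0] * x + dR[1, 0] * y + dR[2, 0] * z + c[0]
    out[1] = dR[0, 1] * x + dR[1, 1] * y + dR[2, 1] * z + c[1]
    out[2] = dR[0, 2] * x + dR[1, 2] * y + dR[2, 2] * z + c[2]


@njit(cache=True)
def _fwd_transform_point(p, dR, c, dt, out):
    # out = dR (p - c) + c + dt
    x = p[0] - c[0]
    y = p[1] - c[1]
    z = p[2] - c[2]
    out[0] = dR[0, 0] * x + dR[0, 1] * y + dR[0, 2] * z + c[0] + dt[0]
    out[1] = dR[1, 0] * x + dR[1, 1] * y + dR[1, 2] * z + c[1] + dt[1]
    out[2] = dR[2, 0] * x + dR[2, 1] * y + dR[2, 2] * z + c[2] + dt[2]


@njit(cache=True)
def _sub_local_energy(sub, i, pos, s2, eps, rc2, r0, kb, ba, ta,
                      sbd_w, nbd_w, lnk, nbd_c, nbd_r, rc):
    """Energy terms that involve free substrate bead i placed at ``pos``."""
    n = sub.shape[0]
    e = _bond(pos[0], pos[1], pos[2], sub[i - 1, 0], sub[i - 1, 1], sub[i - 1, 2], r0, kb)
    if i + 1 < n:
        e += _bond(pos[0], pos[1], pos[2], sub[i + 1, 0], sub[i + 1, 1], sub[i + 1, 2], r0, kb)
    if ba.shape[0] > 0 or ta.shape[0] > 0:
        ox = sub[i, 0]
        oy = sub[i, 1]
        oz = sub[i, 2]
        sub[i, 0] = pos[0]
        sub[i, 1] = pos[1]
        sub[i, 2] = pos[2]
        if ba.shape[0] > 0:
            for j in range(max(1, i - 1), min(n - 2, i + 1) + 1):
                e += _bend(sub[j - 1], sub[j], sub[j + 1], ba)
        if ta.shape[0] > 0:
            for k in range(max(0, i - 3), min(n - 4, i) + 1):
                e += _tors(sub[k], sub[k + 1], sub[k + 2], sub[k + 3], ta)
        sub[i, 0] = ox
        sub[i, 1] = oy
        sub[i, 2] = oz
    # excluded volume vs other substrate beads (skip bonded neighbours)
    for j in range(n):
        if i - 1 <= j <= i + 1:
            continue
        dx = pos[0] - sub[j, 0]
        dy = pos[1] - sub[j, 1]
        dz = pos[2] - sub[j, 2]
        e += _wca(dx * dx + dy * dy + dz * dz, s2, eps, rc2)
    e += _e_point_set(pos[0], pos[1], pos[2], sbd_w, s2, eps, rc2, -1)
    e += _e_point_set(pos[0], pos[1], pos[2], lnk, s2, eps, rc2, -1)
    # NBD with a bounding-sphere pre-check
    dx = pos[0] - nbd_c[0]
    dy = pos[1] - nbd_c[1]
    dz = pos[2] - nbd_c[2]
    if np.sqrt(dx * dx + dy * dy + dz * dz) < nbd_r + rc:
        e += _e_point_set(pos[0], pos[1], pos[2], nbd_w, s2, eps, rc2, -1)
    return e


@njit(cache=True)
def _lnk_local_energy(lnk, k, pos, s2, eps, rc2, r0, kb, ba,
                      sub, sbd_w, nbd_w, ia_s, ia_n, sbd_c, sbd_r, nbd_c, nbd_r, rc):
    """Energy terms involving linker bead k placed at ``pos``.

    The bonded chain is NBD-anchor, l0 ... l(nl-1), SBD-anchor; bends are
    centred on linker beads only.
    """
    nl = lnk.shape[0]
    e = 0.0
    old = np.empty(3)
    old[0] = lnk[k, 0]
    old[1] = lnk[k, 1]
    old[2] = lnk[k, 2]
    lnk[k, 0] = pos[0]
    lnk[k, 1] = pos[1]
    lnk[k, 2] = pos[2]
    # bonds
    if k == 0:
        e += _bond(pos[0], pos[1], pos[2], nbd_w[ia_n, 0], nbd_w[ia_n, 1], nbd_w[ia_n, 2], r0, kb)
    else:
        e += _bond(pos[0], pos[1], pos[2], lnk[k - 1, 0], lnk[k - 1, 1], lnk[k - 1, 2], r0, kb)
    if k == nl - 1:
        e += _bond(pos[0], pos[1], pos[2], sbd_w[ia_s, 0], sbd_w[ia_s, 1], sbd_w[ia_s, 2], r0, kb)
    else:
        e += _bond(pos[0], pos[1], pos[2], lnk[k + 1, 0], lnk[k + 1, 1], lnk[k + 1, 2], r0, kb)
    # bends centred at k-1, k, k+1 (linker beads only)
    if ba.shape[0] > 0:
        for c in range(k - 1, k + 2):
            if c < 0 or c >= nl:
                continue
            pa = nbd_w[ia_n] if c - 1 < 0 else lnk[c - 1]
            pb = lnk[c]
            pc = sbd_w[ia_s] if c + 1 >= nl else lnk[c + 1]
            e += _bend(pa, pb, pc, ba)
    lnk[k, 0] = old[0]
    lnk[k, 1] = old[1]
    lnk[k, 2] = old[2]
    # excluded volume: vs substrate, other linker beads (non-bonded), domains
    e += _e_point_set(pos[0], pos[1], pos[2], sub, s2, eps, rc2, -1)
    for j in range(nl):
        if k - 1 <= j <= k + 1:
            continue
        dx = pos[0] - lnk[j, 0]
        dy = pos[1] - lnk[j, 1]
        dz = pos[2] - lnk[j, 2]
        e += _wca(dx * dx + dy * dy + dz * dz, s2, eps, rc2)
    dx = pos[0] - sbd_c[0]
    dy = pos[1] - sbd_c[1]
    dz = pos[2] - sbd_c[2]
    if np.sqrt(dx * dx + dy * dy + dz * dz) < sbd_r + rc:
        skip = ia_s if k == nl - 1 else -1
        e += _e_point_set(pos[0], pos[1], pos[2], sbd_w, s2, eps, rc2, skip)
    dx = pos[0] - nbd_c[0]
    dy = pos[1] - nbd_c[1]
    dz = pos[2] - nbd_c[2]
    if np.sqrt(dx * dx + dy * dy + dz * dz) < nbd_r + rc:
        skip = ia_n if k == 0 else -1
        e += _e_point_set(pos[0], pos[1], pos[2], nbd_w, s2, eps, rc2, skip)
    return e


@njit(cache=True)
def run_sampler(
    n_sweeps, thin, seed,
    sub, clamp_ref, sbd_ref, nbd_ref, lnk,
    R_s, t_s, R_n, t_n,
    ia_s, ia_n,
    sigma, eps, r0, kb, ba, ta,
    step_sub, crank_sub, step_lnk, crank_lnk,
    rot_sbd_axis, rot_sbd_small, trans_sbd, rot_nbd, trans_nbd, rot_arm,
    rot_pivot,
    indicators, acc,
):
    """Run ``n_sweeps`` sweeps; record one 0/1 non-overlap indicator per
    ``thin`` sweeps into ``indicators`` (if non-empty).  Mutates the state
    arrays and the pose matrices in place; fills ``acc`` (5, 2) with
    (attempts, accepts) per move class."""
    np.random.seed(seed)
    n = sub.shape[0]
    nl = lnk.shape[0]
    s2 = sigma * sigma
    rc2 = 2.0 ** (1.0 / 3.0) * s2
    rc = np.sqrt(rc2)

    sbd_w = np.empty_like(sbd_ref)
    nbd_w = np.empty_like(nbd_ref)
    _apply_pose(sbd_ref, R_s, t_s, sbd_w)
    _apply_pose(nbd_ref, R_n, t_n, nbd_w)
    _apply_pose(clamp_ref, R_s, t_s, sub[0:7])

    # bounding radii (invariant under rigid motion)
    sbd_cref = np.zeros(3)
    for i in range(sbd_ref.shape[0]):
        for d in range(3):
            sbd_cref[d] += sbd_ref[i, d]
    sbd_cref /= sbd_ref.shape[0]
    sbd_rad = 0.0
    for i in range(sbd_ref.shape[0]):
        dx = sbd_ref[i, 0] - sbd_cref[0]
        dy = sbd_ref[i, 1] - sbd_cref[1]
        dz = sbd_ref[i, 2] - sbd_cref[2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r > sbd_rad:
            sbd_rad = r
    nbd_cref = np.zeros(3)
    for i in range(nbd_ref.shape[0]):
        for d in range(3):
            nbd_cref[d] += nbd_ref[i, d]
    nbd_cref /= nbd_ref.shape[0]
    nbd_rad = 0.0
    for i in range(nbd_ref.shape[0]):
        dx = nbd_ref[i, 0] - nbd_cref[0]
        dy = nbd_ref[i, 1] - nbd_cref[1]
        dz = nbd_ref[i, 2] - nbd_cref[2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r > nbd_rad:
            nbd_rad = r

    sbd_c = np.empty(3)
    nbd_c = np.empty(3)

    def_c = np.empty(3)  # scratch

    pos = np.empty(3)
    tmp = np.empty(3)
    dt = np.empty(3)
    zero3 = np.zeros(3)

    n_free = n - 8  # beads 7 .. n-2
    rec = 0

    for sweep in range(n_sweeps):
        # current unit centres
        for d in range(3):
            sbd_c[d] = R_s[d, 0] * sbd_cref[0] + R_s[d, 1] * sbd_cref[1] + R_s[d, 2] * sbd_cref[2] + t_s[d]
            nbd_c[d] = R_n[d, 0] * nbd_cref[0] + R_n[d, 1] * nbd_cref[1] + R_n[d, 2] * nbd_cref[2] + t_n[d]

        # --- free substrate beads: displacement or crankshaft ---------
        for i in range(7, n - 1):
            acc[MOVE_SUB, 0] += 1
            if np.random.random() < 0.5:
                pos[0] = sub[i, 0] + step_sub * np.random.normal()
                pos[1] = sub[i, 1] + step_sub * np.random.normal()
                pos[2] = sub[i, 2] + step_sub * np.random.normal()
            else:
                # crankshaft about the axis through the two chain neighbours:
                # preserves both bond lengths exactly
                ux = sub[i + 1, 0] - sub[i - 1, 0]
                uy = sub[i + 1, 1] - sub[i - 1, 1]
                uz = sub[i + 1, 2] - sub[i - 1, 2]
                nrm = np.sqrt(ux * ux + uy * uy + uz * uz)
                if nrm < 1e-9:
                    continue
                dRc = _axis_rotation(ux / nrm, uy / nrm, uz / nrm,
                                     crank_sub * np.random.normal())
                _fwd_transform_point(sub[i], dRc, sub[i - 1], zero3, pos)
            if pos[2] < 0.0:
                continue
            e_old = _sub_local_energy(sub, i, sub[i], s2, eps, rc2, r0, kb, ba, ta,
                                      sbd_w, nbd_w, lnk, nbd_c, nbd_rad, rc)
            e_new = _sub_local_energy(sub, i, pos, s2, eps, rc2, r0, kb, ba, ta,
                                      sbd_w, nbd_w, lnk, nbd_c, nbd_rad, rc)
            de = e_new - e_old
            if de <= 0.0 or np.random.random() < np.exp(-de):
                sub[i, 0] = pos[0]
                sub[i, 1] = pos[1]
                sub[i, 2] = pos[2]
                acc[MOVE_SUB, 1] += 1

        # --- linker beads: displacement or crankshaft -----------------
        for _ in range(nl):
            k = np.random.randint(0, nl)
            acc[MOVE_LNK, 0] += 1
            if np.random.random() < 0.5:
                pos[0] = lnk[k, 0] + step_lnk * np.random.normal()
                pos[1] = lnk[k, 1] + step_lnk * np.random.normal()
                pos[2] = lnk[k, 2] + step_lnk * np.random.normal()
            else:
                prev = nbd_w[ia_n] if k == 0 else lnk[k - 1]
                nxt = sbd_w[ia_s] if k == nl - 1 else lnk[k + 1]
                ux = nxt[0] - prev[0]
                uy = nxt[1] - prev[1]
                uz = nxt[2] - prev[2]
                nrm = np.sqrt(ux * ux + uy * uy + uz * uz)
                if nrm < 1e-9:
                    continue
                dRc = _axis_rotation(ux / nrm, uy / nrm, uz / nrm,
                                     crank_lnk * np.random.normal())
                _fwd_transform_point(lnk[k], dRc, prev, zero3, pos)
            e_old = _lnk_local_energy(lnk, k, lnk[k], s2, eps, rc2, r0, kb, ba,
                                      sub, sbd_w, nbd_w, ia_s, ia_n,
                                      sbd_c, sbd_rad, nbd_c, nbd_rad, rc)
            e_new = _lnk_local_energy(lnk, k, pos, s2, eps, rc2, r0, kb, ba,
                                      sub, sbd_w, nbd_w, ia_s, ia_n,
                                      sbd_c, sbd_rad, nbd_c, nbd_rad, rc)
            de = e_new - e_old
            if de <= 0.0 or np.random.random() < np.exp(-de):
                lnk[k, 0] = pos[0]
                lnk[k, 1] = pos[1]
                lnk[k, 2] = pos[2]
                acc[MOVE_LNK, 1] += 1

        # --- rigid SBD-unit moves -------------------------------------
        # (a) rotation about the axis through the chain attachment (clamp
        #     bead 7, i.e. sub[6]) and the linker anchor: preserves both
        #     connecting bonds exactly, so large angles are possible;
        # (b) small general rotation about sub[6] plus a small translation.
        for _ in range(2):
            acc[MOVE_SBD, 0] += 1
            for d in range(3):
                def_c[d] = sub[6, d]
            if np.random.random() < 0.5:
                ux = sbd_w[ia_s, 0] - def_c[0]
                uy = sbd_w[ia_s, 1] - def_c[1]
                uz = sbd_w[ia_s, 2] - def_c[2]
                nrm = np.sqrt(ux * ux + uy * uy + uz * uz)
                if nrm < 1e-9:
                    continue
                dR = _axis_rotation(ux / nrm, uy / nrm, uz / nrm,
                                    rot_sbd_axis * np.random.normal())
                for d in range(3):
                    dt[d] = 0.0
            else:
                dR = _rand_rotation(rot_sbd_small)
                for d in range(3):
                    dt[d] = trans_sbd * np.random.normal()
            # wall check for clamp beads under the proposal
            ok = True
            for i in range(7):
                _fwd_transform_point(sub[i], dR, def_c, dt, tmp)
                if tmp[2] < 0.0:
                    ok = False
                    break
            if not ok:
                continue
            de = _sbd_move_delta(sub, lnk, sbd_w, nbd_w, clamp_ref, ia_s, ia_n,
                                 dR, def_c, dt, s2, eps, rc2, rc, r0, kb, ba, ta,
                                 sbd_c, sbd_rad, nbd_c, nbd_rad)
            if de <= 0.0 or np.random.random() < np.exp(-de):
                acc[MOVE_SBD, 1] += 1
                _compose_pose(R_s, t_s, dR, def_c, dt)
                _apply_pose(sbd_ref, R_s, t_s, sbd_w)
                _apply_pose(clamp_ref, R_s, t_s, sub[0:7])
                for d in range(3):
                    sbd_c[d] = (R_s[d, 0] * sbd_cref[0] + R_s[d, 1] * sbd_cref[1]
                                + R_s[d, 2] * sbd_cref[2] + t_s[d])

        # --- rigid NBD / arm moves ------------------------------------
        # (a) rotation about the linker anchor (preserves the anchor bond);
        # (b) small translation (lets the domain diffuse with the linker);
        # (c) swing of the whole NBD + linker arm about the SBD anchor
        #     (bond-preserving; the dominant relaxation of the NBD position)
        for _ in range(3):
            acc[MOVE_NBD, 0] += 1
            u = np.random.random()
            if u < 2.0 / 3.0:
                arm = False
                for d in range(3):
                    def_c[d] = nbd_w[ia_n, d]
                if u < 1.0 / 3.0:
                    dR = _rand_rotation(rot_nbd)
                    for d in range(3):
                        dt[d] = 0.0
                else:
                    dR = _rand_rotation(0.0)
                    for d in range(3):
                        dt[d] = trans_nbd * np.random.normal()
                de = _nbd_move_delta(sub, lnk, sbd_w, nbd_w, ia_s, ia_n,
                                     dR, def_c, dt, s2, eps, rc2, rc, r0, kb, ba,
                                     sbd_c, sbd_rad, nbd_c, nbd_rad)
            else:
                arm = True
                dR = _rand_rotation(rot_arm)
                for d in range(3):
                    def_c[d] = sbd_w[ia_s, d]
                    dt[d] = 0.0
                de = _arm_move_delta(sub, lnk, sbd_w, nbd_w, ia_s, ia_n,
                                     dR, def_c, s2, eps, rc2, rc, ba,
                                     nbd_c, nbd_rad)
            if de <= 0.0 or np.random.random() < np.exp(-de):
                acc[MOVE_NBD, 1] += 1
                if arm:
                    for k in range(nl):
                        _fwd_transform_point(lnk[k], dR, def_c, zero3, tmp)
                        lnk[k, 0] = tmp[0]
                        lnk[k, 1] = tmp[1]
                        lnk[k, 2] = tmp[2]
                _compose_pose(R_n, t_n, dR, def_c, dt)
                _apply_pose(nbd_ref, R_n, t_n, nbd_w)
                for d in range(3):
                    nbd_c[d] = (R_n[d, 0] * nbd_cref[0] + R_n[d, 1] * nbd_cref[1]
                                + R_n[d, 2] * nbd_cref[2] + t_n[d])

        # --- pivot moves ----------------------------------------------
        for _ in range(2):
            acc[MOVE_PIVOT, 0] += 1
            j = np.random.randint(7, n)  # pivot bead index (7 .. n-1)
            dR = _rand_rotation(rot_pivot)
            for d in range(3):
                def_c[d] = sub[j, d]
            # wall check: moved substrate beads 0 .. j-1
            ok = True
            for i in range(j):
                _fwd_transform_point(sub[i], dR, def_c, zero3, tmp)
                if tmp[2] < 0.0:
                    ok = False
                    break
            if not ok:
                continue
            de = _pivot_move_delta(sub, lnk, sbd_w, nbd_w, j, dR, def_c,
                                   s2, eps, rc2, r0, kb, ba, ta)
            if de <= 0.0 or np.random.random() < np.exp(-de):
                acc[MOVE_PIVOT, 1] += 1
                for i in range(j):
                    _fwd_transform_point(sub[i], dR, def_c, zero3, tmp)
                    sub[i, 0] = tmp[0]
                    sub[i, 1] = tmp[1]
                    sub[i, 2] = tmp[2]
                for k in range(nl):
                    _fwd_transform_point(lnk[k], dR, def_c, zero3, tmp)
                    lnk[k, 0] = tmp[0]
                    lnk[k, 1] = tmp[1]
                    lnk[k, 2] = tmp[2]
                _compose_pose(R_s, t_s, dR, def_c, zero3)
                _compose_pose(R_n, t_n, dR, def_c, zero3)
                _apply_pose(sbd_ref, R_s, t_s, sbd_w)
                _apply_pose(nbd_ref, R_n, t_n, nbd_w)
                _apply_pose(clamp_ref, R_s, t_s, sub[0:7])
                for d in range(3):
                    sbd_c[d] = (R_s[d, 0] * sbd_cref[0] + R_s[d, 1] * sbd_cref[1]
                                + R_s[d, 2] * sbd_cref[2] + t_s[d])
                    nbd_c[d] = (R_n[d, 0] * nbd_cref[0] + R_n[d, 1] * nbd_cref[1]
                                + R_n[d, 2] * nbd_cref[2] + t_n[d])

        # --- record ----------------------------------------------------
        if indicators.shape[0] > 0 and sweep % thin == 0:
            minz = 1e30
            for i in range(sbd_w.shape[0]):
                if sbd_w[i, 2] < minz:
                    minz = sbd_w[i, 2]
            for i in range(nbd_w.shape[0]):
                if nbd_w[i, 2] < minz:
                    minz = nbd_w[i, 2]
            for i in range(nl):
                if lnk[i, 2] < minz:
                    minz = lnk[i, 2]
            if rec < indicators.shape[0]:
                indicators[rec] = 1 if minz >= 0.0 else 0
                rec += 1
    return rec


@njit(cache=True)
def _compose_pose(R, t, dR, c, dt):
    """Update pose (R, t) by the world-frame motion x -> dR (x - c) + c + dt."""
    Rn = np.empty((3, 3))
    for i in range(3):
        for j in range(3):
            Rn[i, j] = dR[i, 0] * R[0, j] + dR[i, 1] * R[1, j] + dR[i, 2] * R[2, j]
    tn = np.empty(3)
    for i in range(3):
        tn[i] = dR[i, 0] * (t[0] - c[0]) + dR[i, 1] * (t[1] - c[1]) + dR[i, 2] * (t[2] - c[2]) + c[i] + dt[i]
    for i in range(3):
        for j in range(3):
            R[i, j] = Rn[i, j]
        t[i] = tn[i]
    _orthonormalize(R)


@njit(cache=True)
def _sbd_move_delta(sub, lnk, sbd_w, nbd_w, clamp_ref, ia_s, ia_n,
                    dR, c, dt, s2, eps, rc2, rc, r0, kb, ba, ta,
                    sbd_c, sbd_rad, nbd_c, nbd_rad):
    """Energy change for a rigid move of the SBD unit (domain + clamp).

    Static partners: free substrate beads (7..n-1), linker, NBD.  Pair terms
    use the inverse-transform trick; the few bonded terms at the clamp/chain
    and linker/SBD junctions are evaluated with explicitly moved points.
    """
    n = sub.shape[0]
    nl = lnk.shape[0]
    inv = np.empty(3)
    moved = np.empty(3)
    de = 0.0

    # pair terms: each static bead vs current unit coords, inverse-transformed
    for i in range(7, n):
        _inv_transform_point(sub[i], dR, c, dt, inv)
        e_new = _e_point_set(inv[0], inv[1], inv[2], sbd_w, s2, eps, rc2, -1)
        e_old = _e_point_set(sub[i, 0], sub[i, 1], sub[i, 2], sbd_w, s2, eps, rc2, -1)
        for q in range(7):
            if i == 7 and q == 6:
                continue  # bonded pair (clamp end, first free bead)
            dx = inv[0] - sub[q, 0]
            dy = inv[1] - sub[q, 1]
            dz = inv[2] - sub[q, 2]
            e_new += _wca(dx * dx + dy * dy + dz * dz, s2, eps, rc2)
            dx = sub[i, 0] - sub[q, 0]
            dy = sub[i, 1] - sub[q, 1]
            dz = sub[i, 2] - sub[q, 2]
            e_old += _wca(dx * dx + dy * dy + dz * dz, s2, eps, rc2)
        de += e_new - e_old
    for k in range(nl):
        _inv_transform_point(lnk[k], dR, c, dt, inv)
        skip = ia_s if k == nl - 1 else -1
        e_new = _e_point_set(inv[0], inv[1], inv[2], sbd_w, s2, eps, rc2, skip)
        e_old = _e_point_set(lnk[k, 0], lnk[k, 1], lnk[k, 2], sbd_w, s2, eps, rc2, skip)
        for q in range(7):
            dx = inv[0] - sub[q, 0]
            dy = inv[1] - sub[q, 1]
            dz = inv[2] - sub[q, 2]
            e_new += _wca(dx * dx + dy * dy + dz * dz, s2, eps, rc2)
            dx = lnk[k, 0] - sub[q, 0]
            dy = lnk[k, 1] - sub[q, 1]
            dz = lnk[k, 2] - sub[q, 2]
            e_old += _wca(dx * dx + dy * dy + dz * dz, s2, eps, rc2)
        de += e_new - e_old
    # NBD vs SBD unit.  The bead-vs-unit bounding check is exact when done
    # both on the current position and on the inverse-transformed one (the
    # latter equals the distance of the static bead to the proposed unit).
    # +15 A margin so the clamp (which sticks out of the domain's bounding
    # sphere) is always covered
    reach = sbd_rad + rc + 15.0
    for i in range(nbd_w.shape[0]):
        _inv_transform_point(nbd_w[i], dR, c, dt, inv)
        dx = nbd_w[i, 0] - sbd_c[0]
        dy = nbd_w[i, 1] - sbd_c[1]
        dz = nbd_w[i, 2] - sbd_c[2]
        d_old = np.sqrt(dx * dx + dy * dy + dz * dz)
        dx = inv[0] - sbd_c[0]
        dy = inv[1] - sbd_c[1]
        dz = inv[2] - sbd_c[2]
        d_new = np.sqrt(dx * dx + dy * dy + dz * dz)
        if d_old > reach and d_new > reach:
            continue
        e_new = _e_point_set(inv[0], inv[1], inv[2], sbd_w, s2, eps, rc2, -1)
        e_old = _e_point_set(nbd_w[i, 0], nbd_w[i, 1], nbd_w[i, 2], sbd_w, s2, eps, rc2, -1)
        for q in range(7):
            dx = inv[0] - sub[q, 0]
            dy = inv[1] - sub[q, 1]
            dz = inv[2] - sub[q, 2]
            e_new += _wca(dx * dx + dy * dy + dz * dz, s2, eps, rc2)
            dx = nbd_w[i, 0] - sub[q, 0]
            dy = nbd_w[i, 1] - sub[q, 1]
            dz = nbd_w[i, 2] - sub[q, 2]
            e_old += _wca(dx * dx + dy * dy + dz * dz, s2, eps, rc2)
        de += e_new - e_old

    # bonded terms: clamp-chain junction
    _fwd_transform_point(sub[6], dR, c, dt, moved)
    de += _bond(moved[0], moved[1], moved[2], sub[7, 0], sub[7, 1], sub[7, 2], r0, kb)
    de -= _bond(sub[6, 0], sub[6, 1], sub[6, 2], sub[7, 0], sub[7, 1], sub[7, 2], r0, kb)
    if ba.shape[0] > 0:
        m5 = np.empty(3)
        _fwd_transform_point(sub[5], dR, c, dt, m5)
        de += _bend(m5, moved, sub[7], ba) - _bend(sub[5], sub[6], sub[7], ba)
        if n >= 9:
            de += _bend(moved, sub[7], sub[8], ba) - _bend(sub[6], sub[7], sub[8], ba)
    if ta.shape[0] > 0:
        m4 = np.empty(3)
        m5b = np.empty(3)
        _fwd_transform_point(sub[4], dR, c, dt, m4)
        _fwd_transform_point(sub[5], dR, c, dt, m5b)
        de += _tors(m4, m5b, moved, sub[7], ta) - _tors(sub[4], sub[5], sub[6], sub[7], ta)
        if n >= 9:
            de += _tors(m5b, moved, sub[7], sub[8], ta) - _tors(sub[5], sub[6], sub[7], sub[8], ta)
        if n >= 10:
            de += _tors(moved, sub[7], sub[8], sub[9], ta) - _tors(sub[6], sub[7], sub[8], sub[9], ta)
    # linker / SBD-anchor junction
    anchor_new = np.empty(3)
    _fwd_transform_point(sbd_w[ia_s], dR, c, dt, anchor_new)
    de += _bond(anchor_new[0], anchor_new[1], anchor_new[2],
                lnk[nl - 1, 0], lnk[nl - 1, 1], lnk[nl - 1, 2], r0, kb)
    de -= _bond(sbd_w[ia_s, 0], sbd_w[ia_s, 1], sbd_w[ia_s, 2],
                lnk[nl - 1, 0], lnk[nl - 1, 1], lnk[nl - 1, 2], r0, kb)
    if ba.shape[0] > 0:
        prev = nbd_w[ia_n] if nl == 1 else lnk[nl - 2]
        de += _bend(prev, lnk[nl - 1], anchor_new, ba)
        de -= _bend(prev, lnk[nl - 1], sbd_w[ia_s], ba)
    return de


@njit(cache=True)
def _nbd_move_delta(sub, lnk, sbd_w, nbd_w, ia_s, ia_n,
                    dR, c, dt, s2, eps, rc2, rc, r0, kb, ba,
                    sbd_c, sbd_rad, nbd_c, nbd_rad):
    """Energy change for a rigid move of the NBD."""
    n = sub.shape[0]
    nl = lnk.shape[0]
    inv = np.empty(3)
    de = 0.0
    reach = nbd_rad + rc
    for i in range(n):
        _inv_transform_point(sub[i], dR, c, dt, inv)
        if (_dist(sub[i], nbd_c) > reach) and (_dist(inv, nbd_c) > reach):
            continue
        de += _e_point_set(inv[0], inv[1], inv[2], nbd_w, s2, eps, rc2, -1)
        de -= _e_point_set(sub[i, 0], sub[i, 1], sub[i, 2], nbd_w, s2, eps, rc2, -1)
    for k in range(nl):
        skip = ia_n if k == 0 else -1
        _inv_transform_point(lnk[k], dR, c, dt, inv)
        de += _e_point_set(inv[0], inv[1], inv[2], nbd_w, s2, eps, rc2, skip)
        de -= _e_point_set(lnk[k, 0], lnk[k, 1], lnk[k, 2], nbd_w, s2, eps, rc2, skip)
    for i in range(sbd_w.shape[0]):
        _inv_transform_point(sbd_w[i], dR, c, dt, inv)
        if (_dist(sbd_w[i], nbd_c) > reach) and (_dist(inv, nbd_c) > reach):
            continue
        de += _e_point_set(inv[0], inv[1], inv[2], nbd_w, s2, eps, rc2, -1)
        de -= _e_point_set(sbd_w[i, 0], sbd_w[i, 1], sbd_w[i, 2], nbd_w, s2, eps, rc2, -1)
    # bonded junction NBD-anchor -- linker bead 0
    moved = np.empty(3)
    _fwd_transform_point(nbd_w[ia_n], dR, c, dt, moved)
    de += _bond(moved[0], moved[1], moved[2], lnk[0, 0], lnk[0, 1], lnk[0, 2], r0, kb)
    de -= _bond(nbd_w[ia_n, 0], nbd_w[ia_n, 1], nbd_w[ia_n, 2], lnk[0, 0], lnk[0, 1], lnk[0, 2], r0, kb)
    if ba.shape[0] > 0:
        nxt = sbd_w[ia_s] if nl == 1 else lnk[1]
        de += _bend(moved, lnk[0], nxt, ba)
        de -= _bend(nbd_w[ia_n], lnk[0], nxt, ba)
    return de


@njit(cache=True)
def _arm_move_delta(sub, lnk, sbd_w, nbd_w, ia_s, ia_n, dR, c,
                    s2, eps, rc2, rc, ba, nbd_c, nbd_rad):
    """Energy change for a rigid swing of the NBD + linker arm about the
    SBD linker-anchor point.  All bonds are preserved exactly; only the
    bend at the last linker bead and the arm's excluded-volume contacts
    with the substrate and the SBD change."""
    n = sub.shape[0]
    nl = lnk.shape[0]
    inv = np.empty(3)
    zero3 = np.zeros(3)
    de = 0.0
    reach = nbd_rad + rc
    for i in range(n):
        _inv_transform_point(sub[i], dR, c, zero3, inv)
        if not ((_dist(sub[i], nbd_c) > reach) and (_dist(inv, nbd_c) > reach)):
            de += _e_point_set(inv[0], inv[1], inv[2], nbd_w, s2, eps, rc2, -1)
            de -= _e_point_set(sub[i, 0], sub[i, 1], sub[i, 2], nbd_w, s2, eps, rc2, -1)
        de += _e_point_set(inv[0], inv[1], inv[2], lnk, s2, eps, rc2, -1)
        de -= _e_point_set(sub[i, 0], sub[i, 1], sub[i, 2], lnk, s2, eps, rc2, -1)
    for i in range(sbd_w.shape[0]):
        _inv_transform_point(sbd_w[i], dR, c, zero3, inv)
        skip = nl - 1 if i == ia_s else -1  # bonded anchor/last-linker pair
        if not ((_dist(sbd_w[i], nbd_c) > reach) and (_dist(inv, nbd_c) > reach)):
            de += _e_point_set(inv[0], inv[1], inv[2], nbd_w, s2, eps, rc2, -1)
            de -= _e_point_set(sbd_w[i, 0], sbd_w[i, 1], sbd_w[i, 2], nbd_w, s2, eps, rc2, -1)
        de += _e_point_set(inv[0], inv[1], inv[2], lnk, s2, eps, rc2, skip)
        de -= _e_point_set(sbd_w[i, 0], sbd_w[i, 1], sbd_w[i, 2], lnk, s2, eps, rc2, skip)
    if ba.shape[0] > 0:
        prev = nbd_w[ia_n] if nl == 1 else lnk[nl - 2]
        new_prev = np.empty(3)
        new_last = np.empty(3)
        _fwd_transform_point(prev, dR, c, zero3, new_prev)
        _fwd_transform_point(lnk[nl - 1], dR, c, zero3, new_last)
        de += _bend(new_prev, new_last, sbd_w[ia_s], ba)
        de -= _bend(prev, lnk[nl - 1], sbd_w[ia_s], ba)
    return de


@njit(cache=True)
def _pivot_move_delta(sub, lnk, sbd_w, nbd_w, j, dR, c,
                      s2, eps, rc2, r0, kb, ba, ta):
    """Energy change for a pivot about substrate bead j.

    Moved set: substrate beads 0..j-1 plus the whole chaperone; static set:
    substrate beads j..n-1.  The bond (j-1, j) is preserved exactly by a
    rotation about bead j.
    """
    n = sub.shape[0]
    nl = lnk.shape[0]
    inv = np.empty(3)
    zero3 = np.zeros(3)
    de = 0.0
    for i in range(j, n):
        _inv_transform_point(sub[i], dR, c, zero3, inv)
        # vs moved substrate beads (skip bonded neighbour pair (j-1, j))
        for q in range(j):
            if i == j and q == j - 1:
                continue
            dx = inv[0] - sub[q, 0]
            dy = inv[1] - sub[q, 1]
            dz = inv[2] - sub[q, 2]
            e_n = _wca(dx * dx + dy * dy + dz * dz, s2, eps, rc2)
            dx = sub[i, 0] - sub[q, 0]
            dy = sub[i, 1] - sub[q, 1]
            dz = sub[i, 2] - sub[q, 2]
            de += e_n - _wca(dx * dx + dy * dy + dz * dz, s2, eps, rc2)
        de += _e_point_set(inv[0], inv[1], inv[2], sbd_w, s2, eps, rc2, -1)
        de -= _e_point_set(sub[i, 0], sub[i, 1], sub[i, 2], sbd_w, s2, eps, rc2, -1)
        de += _e_point_set(inv[0], inv[1], inv[2], nbd_w, s2, eps, rc2, -1)
        de -= _e_point_set(sub[i, 0], sub[i, 1], sub[i, 2], nbd_w, s2, eps, rc2, -1)
        de += _e_point_set(inv[0], inv[1], inv[2], lnk, s2, eps, rc2, -1)
        de -= _e_point_set(sub[i, 0], sub[i, 1], sub[i, 2], lnk, s2, eps, rc2, -1)
    # bending/torsion across the pivot boundary
    if ba.shape[0] > 0 or ta.shape[0] > 0:
        m = np.empty((3, 3))  # moved copies of beads j-3, j-2, j-1 as needed
        for off in range(1, 4):
            idx = j - off
            if idx >= 0:
                _fwd_transform_point(sub[idx], dR, c, zero3, m[off - 1])
    if ba.shape[0] > 0:
        if j - 2 >= 0:
            de += _bend(m[1], m[0], sub[j], ba) - _bend(sub[j - 2], sub[j - 1], sub[j], ba)
        if j <= n - 2 and j - 1 >= 0:
            de += _bend(m[0], sub[j], sub[j + 1], ba) - _bend(sub[j - 1], sub[j], sub[j + 1], ba)
    if ta.shape[0] > 0:
        if j - 3 >= 0:
            de += _tors(m[2], m[1], m[0], sub[j], ta) - _tors(sub[j - 3], sub[j - 2], sub[j - 1], sub[j], ta)
        if j - 2 >= 0 and j + 1 <= n - 1:
            de += _tors(m[1], m[0], sub[j], sub[j + 1], ta) - _tors(sub[j - 2], sub[j - 1], sub[j], sub[j + 1], ta)
        if j - 1 >= 0 and j + 2 <= n - 1:
            de += _tors(m[0], sub[j], sub[j + 1], sub[j + 2], ta) - _tors(sub[j - 1], sub[j], sub[j + 1], sub[j + 2], ta)
    return de
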