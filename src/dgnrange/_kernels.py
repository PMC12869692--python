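"""Numba-compiled numerical kernels.

Everything here works in grid coordinates: the voxel lattice corner sits
at the physical origin (0, 0, 0) and spans ``shape * pitch`` millimetres.
Rays are parametrized from a start point to an end point; traversal is
exact Siddon ray–voxel stepping (incremental boundary crossing), so each
intersected voxel appears exactly once with its chord length.

The Monte Carlo kernel transports photons with the kerma approximation
(electron energy deposited at the interaction site): photoelectric
events absorb the photon, Compton events deposit the recoil-electron
energy and continue the photon with a Klein–Nishina-sampled direction,
Rayleigh events redirect without deposition.  All kernels are
single-threaded and seeded, so results are bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from numba import njit

ELECTRON_REST_KEV = 510.998950


@njit(cache=True)
def siddon(p0x, p0y, p0z, p1x, p1y, p1z, pitch, nx, ny, nz, out_idx, out_len):
    """Exact ray–voxel traversal from p0 to p1 (mm).

    Fills ``out_idx`` (m, 3) and ``out_len`` (m,) in order from p0 to p1
    and returns the number of intersected voxels (0 if the ray misses).
    """
    dx = p1x - p0x
    dy = p1y - p0y
    dz = p1z - p0z
    L = (dx * dx + dy * dy + dz * dz) ** 0.5
    if L <= 0.0:
        return 0
    tmin = 0.0
    tmax = 1.0
    if dx != 0.0:
        t1 = (0.0 - p0x) / dx
        t2 = (nx * pitch - p0x) / dx
        if t1 > t2:
            t1, t2 = t2, t1
        if t1 > tmin:
            tmin = t1
        if t2 < tmax:
            tmax = t2
    elif p0x <= 0.0 or p0x >= nx * pitch:
        return 0
    if dy != 0.0:
        t1 = (0.0 - p0y) / dy
        t2 = (ny * pitch - p0y) / dy
        if t1 > t2:
            t1, t2 = t2, t1
        if t1 > tmin:
            tmin = t1
        if t2 < tmax:
            tmax = t2
    elif p0y <= 0.0 or p0y >= ny * pitch:
        return 0
    if dz != 0.0:
        t1 = (0.0 - p0z) / dz
        t2 = (nz * pitch - p0z) / dz
        if t1 > t2:
            t1, t2 = t2, t1
        if t1 > tmin:
            tmin = t1
        if t2 < tmax:
            tmax = t2
    elif p0z <= 0.0 or p0z >= nz * pitch:
        return 0
    if tmax <= tmin:
        return 0

    t_probe = tmin + (tmax - tmin) * 1e-9
    i = int((p0x + dx * t_probe) / pitch)
    j = int((p0y + dy * t_probe) / pitch)
    k = int((p0z + dz * t_probe) / pitch)
    if i < 0:
        i = 0
    elif i > nx - 1:
        i = nx - 1
    if j < 0:
        j = 0
    elif j > ny - 1:
        j = ny - 1
    if k < 0:
        k = 0
    elif k > nz - 1:
        k = nz - 1

    big = 1e30
    if dx > 0.0:
        sx, tdx, tmx = 1, pitch / dx, ((i + 1) * pitch - p0x) / dx
    elif dx < 0.0:
        sx, tdx, tmx = -1, -pitch / dx, (i * pitch - p0x) / dx
    else:
        sx, tdx, tmx = 0, big, big
    if dy > 0.0:
        sy, tdy, tmy = 1, pitch / dy, ((j + 1) * pitch - p0y) / dy
    elif dy < 0.0:
        sy, tdy, tmy = -1, -pitch / dy, (j * pitch - p0y) / dy
    else:
        sy, tdy, tmy = 0, big, big
    if dz > 0.0:
        sz, tdz, tmz = 1, pitch / dz, ((k + 1) * pitch - p0z) / dz
    elif dz < 0.0:
        sz, tdz, tmz = -1, -pitch / dz, (k * pitch - p0z) / dz
    else:
        sz, tdz, tmz = 0, big, big

    t = tmin
    count = 0
    while True:
        tnext = tmx
        if tmy < tnext:
            tnext = tmy
        if tmz < tnext:
            tnext = tmz
        clipped = False
        if tnext >= tmax:
            tnext = tmax
            clipped = True
        seg = (tnext - t) * L
        if seg > 1e-12:
            out_idx[count, 0] = i
            out_idx[count, 1] = j
            out_idx[count, 2] = k
            out_len[count] = seg
            count += 1
        if clipped:
            break
        if tmx <= tnext:
            i += sx
            tmx += tdx
        if tmy <= tnext:
            j += sy
            tmy += tdy
        if tmz <= tnext:
            k += sz
            tmz += tdz
        if i < 0 or i >= nx or j < 0 or j >= ny or k < 0 or k >= nz:
            break
        t = tnext
    return count


@njit(cache=True)
def project_paths(labels, pitch, srcx, srcy, srcz, det_z, pixel_pitch, npx, npy, out_L):
    """Per-pixel per-material path lengths (mm), shape (npx, npy, 4)."""
    nx, ny, nz = labels.shape
    cap = nx + ny + nz + 4
    idx = np.empty((cap, 3), dtype=np.int64)
    seg = np.empty(cap, dtype=np.float64)
    for a in range(npx):
        px = (a + 0.5) * pixel_pitch
        for b in range(npy):
            py = (b + 0.5) * pixel_pitch
            n = siddon(srcx, srcy, srcz, px, py, det_z, pitch, nx, ny, nz, idx, seg)
            for s in range(n):
                m = labels[idx[s, 0], idx[s, 1], idx[s, 2]]
                out_L[a, b, m] += seg[s]


@njit(cache=True)
def _march(labels, pitch, px, py, pz, dx, dy, dz, mu4, tau_target):
    """Advance a photon to its next interaction or out of the grid.

    Direction (dx, dy, dz) must be unit length; mu4 holds the linear
    attenuation (1/mm) of the four material labels at the photon energy.
    Returns (status, s, i, j, k): status 1 = interaction after path
    length s (mm) inside voxel (i, j, k); status 0 = escaped.
    """
    nx, ny, nz = labels.shape
    smin = 0.0
    smax = 1e30
    if dx != 0.0:
        t1 = (0.0 - px) / dx
        t2 = (nx * pitch - px) / dx
        if t1 > t2:
            t1, t2 = t2, t1
        if t1 > smin:
            smin = t1
        if t2 < smax:
            smax = t2
    elif px <= 0.0 or px >= nx * pitch:
        return 0, 0.0, 0, 0, 0
    if dy != 0.0:
        t1 = (0.0 - py) / dy
        t2 = (ny * pitch - py) / dy
        if t1 > t2:
            t1, t2 = t2, t1
        if t1 > smin:
            smin = t1
        if t2 < smax:
            smax = t2
    elif py <= 0.0 or py >= ny * pitch:
        return 0, 0.0, 0, 0, 0
    if dz != 0.0:
        t1 = (0.0 - pz) / dz
        t2 = (nz * pitch - pz) / dz
        if t1 > t2:
            t1, t2 = t2, t1
        if t1 > smin:
            smin = t1
        if t2 < smax:
            smax = t2
    elif pz <= 0.0 or pz >= nz * pitch:
        return 0, 0.0, 0, 0, 0
    if smax <= smin:
        return 0, 0.0, 0, 0, 0

    s_probe = smin + max(1e-9, (smax - smin) * 1e-12)
    i = int((px + dx * s_probe) / pitch)
    j = int((py + dy * s_probe) / pitch)
    k = int((pz + dz * s_probe) / pitch)
    if i < 0:
        i = 0
    elif i > nx - 1:
        i = nx - 1
    if j < 0:
        j = 0
    elif j > ny - 1:
        j = ny - 1
    if k < 0:
        k = 0
    elif k > nz - 1:
        k = nz - 1

    big = 1e30
    if dx > 0.0:
        sx, tdx, tmx = 1, pitch / dx, ((i + 1) * pitch - px) / dx
    elif dx < 0.0:
        sx, tdx, tmx = -1, -pitch / dx, (i * pitch - px) / dx
    else:
        sx, tdx, tmx = 0, big, big
    if dy > 0.0:
        sy, tdy, tmy = 1, pitch / dy, ((j + 1) * pitch - py) / dy
    elif dy < 0.0:
        sy, tdy, tmy = -1, -pitch / dy, (j * pitch - py) / dy
    else:
        sy, tdy, tmy = 0, big, big
    if dz > 0.0:
        sz, tdz, tmz = 1, pitch / dz, ((k + 1) * pitch - pz) / dz
    elif dz < 0.0:
        sz, tdz, tmz = -1, -pitch / dz, (k * pitch - pz) / dz
    else:
        sz, tdz, tmz = 0, big, big

    s = smin
    tau = 0.0
    while True:
        snext = tmx
        if tmy < snext:
            snext = tmy
        if tmz < snext:
            snext = tmz
        clipped = False
        if snext >= smax:
            snext = smax
            clipped = True
        mu = mu4[labels[i, j, k]]
        dtau = mu * (snext - s)
        if tau + dtau >= tau_target:
            s_int = s + (tau_target - tau) / mu
            return 1, s_int, i, j, k
        tau += dtau
        if clipped:
            return 0, smax, i, j, k
        if tmx <= snext:
            i += sx
            tmx += tdx
        if tmy <= snext:
            j += sy
            tmy += tdy
        if tmz <= snext:
            k += sz
            tmz += tdz
        if i < 0 or i >= nx or j < 0 or j >= ny or k < 0 or k >= nz:
            return 0, snext, i, j, k
        s = snext
    return 0, 0.0, 0, 0, 0


@njit(cache=True)
def _sample_compton_costheta(a):
    """Klein–Nishina polar angle cosine by rejection (envelope 2)."""
    while True:
        mu = 2.0 * np.random.random() - 1.0
        x = 1.0 / (1.0 + a * (1.0 - mu))
        g = x * x * (x + 1.0 / x - 1.0 + mu * mu)
        if 2.0 * np.random.random() <= g:
            return mu


@njit(cache=True)
def _sample_rayleigh_costheta():
    """Thomson angular distribution (form factors neglected)."""
    while True:
        mu = 2.0 * np.random.random() - 1.0
        if np.random.random() <= 0.5 * (1.0 + mu * mu):
            return mu


@njit(cache=True)
def _rotate(dx, dy, dz, cost, phi):
    sint = (max(0.0, 1.0 - cost * cost)) ** 0.5
    # orthonormal frame around the current direction
    if abs(dz) < 0.99:
        hx, hy, hz = 0.0, 0.0, 1.0
    else:
        hx, hy, hz = 1.0, 0.0, 0.0
    ux = dy * hz - dz * hy
    uy = dz * hx - dx * hz
    uz = dx * hy - dy * hx
    un = (ux * ux + uy * uy + uz * uz) ** 0.5
    ux /= un
    uy /= un
    uz /= un
    vx = dy * uz - dz * uy
    vy = dz * ux - dx * uz
    vz = dx * uy - dy * ux
    cp = np.cos(phi)
    sp = np.sin(phi)
    nx = cost * dx + sint * (cp * ux + sp * vx)
    ny = cost * dy + sint * (cp * uy + sp * vy)
    nz = cost * dz + sint * (cp * uz + sp * vz)
    n = (nx * nx + ny * ny + nz * nz) ** 0.5
    return nx / n, ny / n, nz / n


@njit(cache=True)
def mc_bin(labels, pitch, srcx, srcy, srcz, det_z, rx1, ry1,
           E0, egrid_min, egrid_step, mu_mm, cum_pe, cum_pec,
           n_photons, seed, n_batches, scatter_on, rayleigh_on,
           kx0, kx1, ky0, ky1, fg_label,
           edep_fg_batch):
    """Transport ``n_photons`` monoenergetic photons of energy E0 (keV).

    Photons are aimed at points uniform over the detector-plane
    rectangle [0, rx1] × [0, ry1] at z = det_z.  ``mu_mm`` is the
    (n_labels, n_egrid) linear-attenuation lookup in 1/mm on the energy
    grid egrid_min + i * egrid_step; ``cum_pe`` / ``cum_pec`` are the
    cumulative photoelectric and photoelectric+Compton probabilities on
    the same grid.  Deposited fibroglandular energy (keV) is accumulated
    per batch in ``edep_fg_batch``; returns (n_kerma, edep_total,
    escaped_total) with the exact energy ledger
    edep_total + escaped_total = n_photons * E0.
    """
    np.random.seed(seed)
    n_egrid = mu_mm.shape[1]
    n_kerma = 0
    edep_total = 0.0
    escaped = 0.0
    mu4 = np.empty(mu_mm.shape[0], dtype=np.float64)
    for p in range(n_photons):
        b = p % n_batches
        tx = rx1 * np.random.random()
        ty = ry1 * np.random.random()
        dx = tx - srcx
        dy = ty - srcy
        dz = det_z - srcz
        n = (dx * dx + dy * dy + dz * dz) ** 0.5
        dx /= n
        dy /= n
        dz /= n
        # entrance kerma tally: crossing of the scoring region at z = 0
        s0 = (0.0 - srcz) / dz
        cx = srcx + dx * s0
        cy = srcy + dy * s0
        if kx0 <= cx <= kx1 and ky0 <= cy <= ky1:
            n_kerma += 1
        E = E0
        px, py, pz = srcx, srcy, srcz
        while True:
            # linear attenuation of each material at the current energy
            fe = (E - egrid_min) / egrid_step
            ie = int(fe)
            if ie < 0:
                ie = 0
            elif ie > n_egrid - 2:
                ie = n_egrid - 2
            w = fe - ie
            if w < 0.0:
                w = 0.0
            elif w > 1.0:
                w = 1.0
            for m in range(mu_mm.shape[0]):
                mu4[m] = mu_mm[m, ie] * (1.0 - w) + mu_mm[m, ie + 1] * w
            tau_target = -np.log(np.random.random())
            status, s, i, j, k = _march(labels, pitch, px, py, pz, dx, dy, dz,
                                        mu4, tau_target)
            if status == 0:
                escaped += E
                break
            px += dx * s
            py += dy * s
            pz += dz * s
            m = labels[i, j, k]
            p_pe = cum_pe[m, ie] * (1.0 - w) + cum_pe[m, ie + 1] * w
            p_pec = cum_pec[m, ie] * (1.0 - w) + cum_pec[m, ie + 1] * w
            u = np.random.random()
            if u < p_pe:
                # photoelectric: full local absorption
                edep_total += E
                if m == fg_label:
                    edep_fg_batch[b] += E
                break
            elif u < p_pec:
                # Compton: deposit recoil energy, continue the photon
                a = E / ELECTRON_REST_KEV
                cost = _sample_compton_costheta(a)
                Eprime = E / (1.0 + a * (1.0 - cost))
                dep = E - Eprime
                edep_total += dep
                if m == fg_label:
                    edep_fg_batch[b] += dep
                if not scatter_on:
                    escaped += Eprime
                    break
                if Eprime < egrid_min:
                    # below the transport cutoff: locally absorbed
                    edep_total += Eprime
                    if m == fg_label:
                        edep_fg_batch[b] += Eprime
                    break
                E = Eprime
                phi = 2.0 * np.pi * np.random.random()
                dx, dy, dz = _rotate(dx, dy, dz, cost, phi)
            else:
                # Rayleigh: redirect, no energy transfer
                if not scatter_on:
                    escaped += E
                    break
                if rayleigh_on:
                    cost = _sample_rayleigh_costheta()
                    phi = 2.0 * np.pi * np.random.random()
                    dx, dy, dz = _rotate(dx, dy, dz, cost, phi)
                # rayleigh_on False: treat as a null event (forward delta)
    return n_kerma, edep_total, escaped


@njit(cache=True)
def primary_bin(labels, pitch, srcx, srcy, srcz, det_z, rx1, ry1,
                E0, mu4, muen_ratio_fg, fg_label, n_sub,
                kx0, kx1, ky0, ky1):
    """Deterministic primary-beam (collision kerma) expectation.

    Integrates Beer–Lambert-attenuated fluence along source→detector
    rays on an n_sub× finer grid than 1 mm pixels; expected energy
    deposited in fibroglandular voxels is fluence × E × (μ_en/μ)_FG per
    interaction.  Returns (mean FG deposit per emitted photon in keV,
    fraction of emitted photons crossing the kerma region).
    """
    nx, ny, nz = labels.shape
    cap = nx + ny + nz + 4
    idx = np.empty((cap, 3), dtype=np.int64)
    seg = np.empty(cap, dtype=np.float64)
    nsx = int(rx1 / pitch) * n_sub
    nsy = int(ry1 / pitch) * n_sub
    dep = 0.0
    cross = 0
    for a in range(nsx):
        tx = (a + 0.5) * rx1 / nsx
        for b in range(nsy):
            ty = (b + 0.5) * ry1 / nsy
            dz = det_z - srcz
            s0 = (0.0 - srcz) / dz
            cx = srcx + (tx - srcx) * s0
            cy = srcy + (ty - srcy) * s0
            if kx0 <= cx <= kx1 and ky0 <= cy <= ky1:
                cross += 1
            n = siddon(srcx, srcy, srcz, tx, ty, det_z, pitch, nx, ny, nz, idx, seg)
            tau = 0.0
            for s in range(n):
                m = labels[idx[s, 0], idx[s, 1], idx[s, 2]]
                dtau = mu4[m] * seg[s]
                if m == fg_label:
                    dep += E0 * muen_ratio_fg * (np.exp(-tau) - np.exp(-tau - dtau))
                tau += dtau
    n_rays = nsx * nsy
    return dep / n_rays, cross / n_rays


@njit(cache=True)
def mark_support(labels, pitch, srcx, srcy, srcz, det_z, pixel_pitch, support):
    """Label every voxel traversed by a supported pixel's ray as adipose."""
    nx, ny, nz = labels.shape
    cap = nx + ny + nz + 4
    idx = np.empty((cap, 3), dtype=np.int64)
    seg = np.empty(cap, dtype=np.float64)
    npx, npy = support.shape
    for a in range(npx):
        px = (a + 0.5) * pixel_pitch
        for b in range(npy):
            if not support[a, b]:
                continue
            py = (b + 0.5) * pixel_pitch
            n = siddon(srcx, srcy, srcz, px, py, det_z, pitch, nx, ny, nz, idx, seg)
            for s in range(n):
                if labels[idx[s, 0], idx[s, 1], idx[s, 2]] == 0:
                    labels[idx[s, 0], idx[s, 1], idx[s, 2]] = 1
    return 0


@njit(cache=True)
def fill_rays(labels, pitch, srcx, srcy, srcz, det_z, pixel_pitch,
              support, target_len, mode, zc_mm):
    """Flip adipose voxels to fibroglandular along each supported ray.

    mode 0 = source-first (maximum dose), 1 = center-out from the
    mid-depth plane zc_mm, 2 = detector-first (minimum dose).  Voxels
    already fibroglandular count toward the ray's budget and are never
    un-flipped.  The last voxel is kept only if that reduces the
    absolute path-length error (half-voxel rule).  Returns the number
    of rays whose target could not be met (clamped rays).
    """
    nx, ny, nz = labels.shape
    cap = nx + ny + nz + 4
    idx = np.empty((cap, 3), dtype=np.int64)
    seg = np.empty(cap, dtype=np.float64)
    order = np.empty(cap, dtype=np.int64)
    run_start = np.empty(cap, dtype=np.int64)
    run_end = np.empty(cap, dtype=np.int64)
    npx, npy = support.shape
    n_clamped = 0
    for a in range(npx):
        px = (a + 0.5) * pixel_pitch
        for b in range(npy):
            if not support[a, b]:
                continue
            target = target_len[a, b]
            if target <= 0.0:
                continue
            py = (b + 0.5) * pixel_pitch
            n = siddon(srcx, srcy, srcz, px, py, det_z, pitch, nx, ny, nz, idx, seg)
            if n == 0:
                n_clamped += 1
                continue
            cum = 0.0
            for s in range(n):
                if labels[idx[s, 0], idx[s, 1], idx[s, 2]] == 2:
                    cum += seg[s]
            if cum >= target:
                continue
            if mode == 0:
                for s in range(n):
                    order[s] = s
            elif mode == 2:
                for s in range(n):
                    order[s] = n - 1 - s
            else:
                # Center-out by depth slice.  Oblique rays cross two
                # voxels within one slice, so the walk must step over
                # whole equal-z runs of the traversal (z is monotone
                # along the ray) or bands would misalign across rays.
                nrun = 0
                s = 0
                while s < n:
                    run_start[nrun] = s
                    z0 = idx[s, 2]
                    while s < n and idx[s, 2] == z0:
                        s += 1
                    run_end[nrun] = s
                    nrun += 1
                r0 = 0
                best = 1e30
                for rr in range(nrun):
                    zc = (idx[run_start[rr], 2] + 0.5) * pitch
                    d = abs(zc - zc_mm)
                    if d < best:
                        best = d
                        r0 = rr
                m_count = 0
                for s in range(run_start[r0], run_end[r0]):
                    order[m_count] = s
                    m_count += 1
                step = 1
                while m_count < n:
                    rr = r0 - step  # one slice up (toward the source) ...
                    if rr >= 0:
                        for s in range(run_start[rr], run_end[rr]):
                            order[m_count] = s
                            m_count += 1
                    rr = r0 + step  # ... then one down
                    if rr < nrun:
                        for s in range(run_start[rr], run_end[rr]):
                            order[m_count] = s
                            m_count += 1
                    step += 1
            done = False
            for t in range(n):
                s = order[t]
                vi, vj, vk = idx[s, 0], idx[s, 1], idx[s, 2]
                if labels[vi, vj, vk] != 1:
                    continue
                new = cum + seg[s]
                if new < target:
                    labels[vi, vj, vk] = 2
                    cum = new
                else:
                    if abs(new - target) <= abs(cum - target):
                        labels[vi, vj, vk] = 2
                        cum = new
                    done = True
                    break
            if not done and cum < target - 0.5 * pitch:
                n_clamped += 1
    return n_clamped
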