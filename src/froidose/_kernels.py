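"""Numba kernels: exact voxel traversal, primary-kerma projection, MC photon
transport.  Units inside kernels: positions mm, lengths converted to cm for
radiological paths, energies keV, attenuation coefficients 1/cm or cm^2/g as
noted.
"""

from __future__ import annotations

import numpy as np
from numba import njit, prange

_EPS = 1e-9


@njit(cache=True)
def _grid_entry(p0, d, lo, hi):
    """Parametric [tmin, tmax] of segment p0 + t*d inside the box, or (1, 0)."""
    tmin, tmax = 0.0, 1.0
    for a in range(3):
        if abs(d[a]) > _EPS:
            t1 = (lo[a] - p0[a]) / d[a]
            t2 = (hi[a] - p0[a]) / d[a]
            if t1 > t2:
                t1, t2 = t2, t1
            if t1 > tmin:
                tmin = t1
            if t2 < tmax:
                tmax = t2
        elif p0[a] < lo[a] or p0[a] > hi[a]:
            return 1.0, 0.0
    return tmin, tmax


@njit(cache=True)
def traverse(p0, p1, origin, spacing, shape, idx_out, len_out):
    """Exact Siddon/Amanatides-Woo traversal of segment p0->p1 (mm).

    Fills flat voxel indices and intersection lengths (mm); returns count.
    """
    lo = origin
    hi = np.empty(3)
    for a in range(3):
        hi[a] = origin[a] + spacing[a] * shape[a]
    d = np.empty(3)
    for a in range(3):
        d[a] = p1[a] - p0[a]
    seg_len = np.sqrt(d[0] ** 2 + d[1] ** 2 + d[2] ** 2)
    if seg_len <= 0.0:
        return 0
    tmin, tmax = _grid_entry(p0, d, lo, hi)
    if tmax <= tmin:
        return 0

    # voxel indices at entry
    i = np.empty(3, dtype=np.int64)
    t = tmin + _EPS
    for a in range(3):
        gi = int(np.floor((p0[a] + t * d[a] - lo[a]) / spacing[a]))
        if gi < 0:
            gi = 0
        if gi >= shape[a]:
            gi = shape[a] - 1
        i[a] = gi

    step = np.empty(3, dtype=np.int64)
    t_next = np.empty(3)
    t_delta = np.empty(3)
    for a in range(3):
        if d[a] > _EPS:
            step[a] = 1
            t_delta[a] = spacing[a] / d[a]
            t_next[a] = ((i[a] + 1) * spacing[a] + lo[a] - p0[a]) / d[a]
        elif d[a] < -_EPS:
            step[a] = -1
            t_delta[a] = -spacing[a] / d[a]
            t_next[a] = (i[a] * spacing[a] + lo[a] - p0[a]) / d[a]
        else:
            step[a] = 0
            t_delta[a] = np.inf
            t_next[a] = np.inf

    n = 0
    t_cur = tmin
    while t_cur < tmax - _EPS:
        a = 0
        if t_next[1] < t_next[a]:
            a = 1
        if t_next[2] < t_next[a]:
            a = 2
        t_stop = t_next[a]
        if t_stop > tmax:
            t_stop = tmax
        dl = (t_stop - t_cur) * seg_len
        if dl > 0.0:
            idx_out[n] = (i[0] * shape[1] + i[1]) * shape[2] + i[2]
            len_out[n] = dl
            n += 1
        t_cur = t_stop
        if t_cur >= tmax - _EPS:
            break
        i[a] += step[a]
        if i[a] < 0 or i[a] >= shape[a]:
            break
        t_next[a] += t_delta[a]
    return n


@njit(cache=True, parallel=True)
def primary_dose_kernel(
    labels,          # (nx,ny,nz) int16
    compute_idx,     # (nv, 3) int32 voxel indices to score
    rho_lab,         # (nlab,) g/cm^3
    mu_mass,         # (nlab, nE) cm^2/g
    dep_mass,        # (nlab, nE) cm^2/g deposition coefficient
    energies,        # (nE,) keV
    weights,         # (nE,) photons per bin, normalized to 1 per scan
    origin, spacing, # (3,) mm
    sources, axes, us, vs,   # (np, 3) mm / unit vectors
    sid_mm, half_u, half_v,  # detector geometry, mm
    r_ap_mm, ap_cx, ap_cy, filt_th_mm,  # aperture (r_ap < 0: no filter)
    filt_od_per_mm,  # (nE,) optical depth per mm of filter path
    dose_out,        # (nx,ny,nz) float64, keV/g per primary
):
    nproj = sources.shape[0]
    nlab = rho_lab.shape[0]
    nE = energies.shape[0]
    shape = np.array(labels.shape, dtype=np.int64)
    nmax = int(shape[0] + shape[1] + shape[2] + 4)
    for vi in prange(compute_idx.shape[0]):
        ii = compute_idx[vi, 0]
        jj = compute_idx[vi, 1]
        kk = compute_idx[vi, 2]
        vc = np.empty(3)
        vc[0] = origin[0] + (ii + 0.5) * spacing[0]
        vc[1] = origin[1] + (jj + 0.5) * spacing[1]
        vc[2] = origin[2] + (kk + 0.5) * spacing[2]
        vlab = labels[ii, jj, kk]
        areal = np.empty(nlab)
        idx_buf = np.empty(nmax, dtype=np.int64)
        len_buf = np.empty(nmax)
        acc = 0.0
        for p in range(nproj):
            dx = vc[0] - sources[p, 0]
            dy = vc[1] - sources[p, 1]
            dz = vc[2] - sources[p, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            ca = (dx * axes[p, 0] + dy * axes[p, 1] + dz * axes[p, 2]) / r
            if ca <= 1e-9:
                continue
            scale = sid_mm / (r * ca)
            hu = (dx * us[p, 0] + dy * us[p, 1] + dz * us[p, 2]) * scale
            hv = (dx * vs[p, 0] + dy * vs[p, 1] + dz * vs[p, 2]) * scale
            if abs(hu) > half_u or abs(hv) > half_v:
                continue
            fpath = 0.0
            if r_ap_mm >= 0.0:
                du = hu - ap_cx
                dv = hv - ap_cy
                if du * du + dv * dv > r_ap_mm * r_ap_mm:
                    fpath = filt_th_mm / ca
            for l in range(nlab):
                areal[l] = 0.0
            n = traverse(sources[p], vc, origin, spacing, shape, idx_buf, len_buf)
            for s in range(n):
                fl = idx_buf[s]
                k2 = fl % shape[2]
                j2 = (fl // shape[2]) % shape[1]
                i2 = fl // (shape[1] * shape[2])
                lab = labels[i2, j2, k2]
                areal[lab] += len_buf[s] * 0.1 * rho_lab[lab]  # g/cm^2
            r_cm = r * 0.1
            inv4pir2 = 1.0 / (4.0 * np.pi * r_cm * r_cm)
            for e in range(nE):
                w = weights[e]
                if w <= 0.0:
                    continue
                od = fpath * filt_od_per_mm[e]
                for l in range(nlab):
                    if areal[l] > 0.0:
                        od += mu_mass[l, e] * areal[l]
                acc += (
                    w * energies[e] * dep_mass[vlab, e] * np.exp(-od) * inv4pir2
                )
        dose_out[ii, jj, kk] = acc


@njit(cache=True)
def _rotate(dx, dy, dz, cos_t, phi):
    """Rotate unit vector by polar angle acos(cos_t) and azimuth phi."""
    sin_t = np.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    # build an orthonormal frame around (dx,dy,dz)
    if abs(dz) < 0.99:
        ux, uy, uz = -dy, dx, 0.0
    else:
        ux, uy, uz = 0.0, -dz, dy
    un = np.sqrt(ux * ux + uy * uy + uz * uz)
    ux, uy, uz = ux / un, uy / un, uz / un
    vx = dy * uz - dz * uy
    vy = dz * ux - dx * uz
    vz = dx * uy - dy * ux
    cp, sp = np.cos(phi), np.sin(phi)
    nx = cos_t * dx + sin_t * (cp * ux + sp * vx)
    ny = cos_t * dy + sin_t * (cp * uy + sp * vy)
    nz = cos_t * dz + sin_t * (cp * uz + sp * vz)
    nn = np.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / nn, ny / nn, nz / nn


@njit(cache=True)
def _sample_kn_eps(k):
    """Klein-Nishina energy-ratio sampling (free electron), k = E/m_e c^2."""
    eps0 = 1.0 / (1.0 + 2.0 * k)
    a1 = -np.log(eps0)
    a2 = 0.5 * (1.0 - eps0 * eps0)
    while True:
        if np.random.random() * (a1 + a2) < a1:
            eps = np.exp(-a1 * np.random.random())
        else:
            eps = np.sqrt(eps0 * eps0 + (1.0 - eps0 * eps0) * np.random.random())
        t = (1.0 - eps) / (k * eps)
        sin2 = t * (2.0 - t)
        if np.random.random() <= 1.0 - eps * sin2 / (1.0 + eps * eps):
            return eps


@njit(cache=True)
def mc_photon_kernel(
    labels, rho_lab,
    mu_lin,          # (nlab, 150) total linear attenuation 1/cm on 1-keV grid
    p_ray, p_comp,   # (nlab, 150) interaction-type fractions
    mu_max,          # (150,) Woodcock majorant, 1/cm
    cdf,             # (150,) emission-energy CDF on the 1-keV grid
    origin, spacing,
    sources, axes, us, vs,
    sid_mm, half_u, half_v, cos_max, omega_frac,
    r_ap_mm, ap_cx, ap_cy, filt_th_mm, filt_od_per_mm,  # (150,)
    histories, seed,
    force_photoelectric,  # disable scatter channels (engine cross-check mode)
    edep,            # (nx,ny,nz) float64, weighted keV
):
    np.random.seed(seed)
    nproj = sources.shape[0]
    nx, ny, nz = labels.shape
    lo0, lo1, lo2 = origin[0], origin[1], origin[2]
    hi0 = lo0 + spacing[0] * nx
    hi1 = lo1 + spacing[1] * ny
    hi2 = lo2 + spacing[2] * nz
    emitted = 0.0
    for h in range(histories):
        p = h % nproj
        # --- emission energy
        u = np.random.random()
        eidx = np.searchsorted(cdf, u)
        if eidx > 149:
            eidx = 149
        energy = eidx + 1.0
        # --- direction: uniform solid angle in the cone cap, then FOV test
        while True:
            ct = 1.0 - np.random.random() * (1.0 - cos_max)
            phi = 2.0 * np.pi * np.random.random()
            st = np.sqrt(1.0 - ct * ct)
            cu = st * np.cos(phi)
            cv = st * np.sin(phi)
            hu = cu * sid_mm / ct
            hv = cv * sid_mm / ct
            if abs(hu) <= half_u and abs(hv) <= half_v:
                break
        dx = axes[p, 0] * ct + us[p, 0] * cu + vs[p, 0] * cv
        dy = axes[p, 1] * ct + us[p, 1] * cu + vs[p, 1] * cv
        dz = axes[p, 2] * ct + us[p, 2] * cu + vs[p, 2] * cv
        w = omega_frac
        emitted += energy * w
        if r_ap_mm >= 0.0:
            du = hu - ap_cx
            dv = hv - ap_cy
            if du * du + dv * dv > r_ap_mm * r_ap_mm:
                w *= np.exp(-filt_od_per_mm[eidx] * filt_th_mm / ct)
        # --- advance to the grid
        px, py, pz = sources[p, 0], sources[p, 1], sources[p, 2]
        p0 = np.empty(3)
        p0[0], p0[1], p0[2] = px, py, pz
        d3 = np.empty(3)
        big = 1.0e5
        d3[0], d3[1], d3[2] = dx * big, dy * big, dz * big
        lo = np.empty(3)
        hi = np.empty(3)
        lo[0], lo[1], lo[2] = lo0, lo1, lo2
        hi[0], hi[1], hi[2] = hi0, hi1, hi2
        tmin, tmax = _grid_entry(p0, d3, lo, hi)
        if tmax <= tmin:
            continue
        px += dx * (tmin * big + 1e-6)
        py += dy * (tmin * big + 1e-6)
        pz += dz * (tmin * big + 1e-6)
        # --- Woodcock tracking
        alive = True
        while alive:
            mm = mu_max[eidx]
            step_mm = -np.log(np.random.random()) / mm * 10.0
            px += dx * step_mm
            py += dy * step_mm
            pz += dz * step_mm
            if px < lo0 or px >= hi0 or py < lo1 or py >= hi1 or pz < lo2 or pz >= hi2:
                break
            i = int((px - lo0) / spacing[0])
            j = int((py - lo1) / spacing[1])
            k = int((pz - lo2) / spacing[2])
            lab = labels[i, j, k]
            if np.random.random() >= mu_lin[lab, eidx] / mm:
                continue  # virtual collision
            if force_photoelectric:
                edep[i, j, k] += energy * w
                break
            xi = np.random.random()
            if xi < p_ray[lab, eidx]:
                # Rayleigh: Thomson angular shape, no energy loss
                while True:
                    ct2 = 2.0 * np.random.random() - 1.0
                    if np.random.random() <= 0.5 * (1.0 + ct2 * ct2):
                        break
                dx, dy, dz = _rotate(dx, dy, dz, ct2, 2.0 * np.pi * np.random.random())
            elif xi < p_ray[lab, eidx] + p_comp[lab, eidx]:
                kk = energy / 511.0
                eps = _sample_kn_eps(kk)
                ct2 = 1.0 - (1.0 / eps - 1.0) / kk
                if ct2 < -1.0:
                    ct2 = -1.0
                new_e = energy * eps
                edep[i, j, k] += (energy - new_e) * w
                energy = new_e
                if energy < 1.0:
                    edep[i, j, k] += energy * w
                    break
                eidx = int(energy - 0.5)
                if eidx > 149:
                    eidx = 149
                if eidx < 0:
                    eidx = 0
                dx, dy, dz = _rotate(dx, dy, dz, ct2, 2.0 * np.pi * np.random.random())
            else:
                edep[i, j, k] += energy * w
                break
    return emitted
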