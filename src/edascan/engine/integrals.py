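"""McMurchie-Davidson Gaussian integrals with numba kernels.

Implements overlap, kinetic, nuclear-attraction and electron-repulsion
integrals over contracted Cartesian Gaussians (s and p shells in the built-in
basis; the recursions are general in the angular index) together with the
density-contracted first derivatives needed for analytic nuclear gradients.

Conventions (Helgaker/Jorgensen/Olsen):
    E_t^{ij}   Hermite expansion coefficients per dimension,
    R_{tuv}    Hermite Coulomb integrals built on the Boys function,
    (ab|cd) = 2 pi^{5/2} / (p q sqrt(p+q)) *
              sum_{tuv} E^{ab} sum_{TUV} E^{cd} (-1)^{T+U+V} R_{t+T,u+U,v+V}.

Derivatives use the angular-momentum increment identity
    d/dA_x (i| = 2a (i+1| - i (i-1|,
applied per primitive, with translational invariance supplying the remaining
centers.  All quantities are in atomic units.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# Array extents for the Hermite tables: 1D angular index <= 3 covers p shells
# plus the +1 (gradients) and +2 (kinetic) increments used internally.
MI = 4
MJ = 5
MT = 10
LMAXR = 8  # R-tensor linear extent (t+u+v <= 7 is ample for s/p gradients)

# Cartesian component tables: offsets per l, then (lx, ly, lz) triples.
_COFF = np.array([0, 1, 4], dtype=np.int64)
_CLX = np.array([0, 1, 0, 0, 2, 1, 1, 0, 0, 0], dtype=np.int64)
_CLY = np.array([0, 0, 1, 0, 0, 1, 0, 2, 1, 0], dtype=np.int64)
_CLZ = np.array([0, 0, 0, 1, 0, 0, 1, 0, 1, 2], dtype=np.int64)


@njit(cache=True)
def _ncomp(l):
    return (l + 1) * (l + 2) // 2


@njit(cache=True)
def _boys(m, T, F):
    """Fill F[0..m] with Boys functions F_k(T)."""
    if T < 1e-13:
        for i in range(m + 1):
            F[i] = 1.0 / (2.0 * i + 1.0)
        return
    if T > 35.0:
        F[0] = 0.5 * math.sqrt(math.pi / T)
        expT = math.exp(-T)
        for i in range(m):
            F[i + 1] = ((2.0 * i + 1.0) * F[i] - expT) * (0.5 / T)
        return
    expT = math.exp(-T)
    s = 1.0 / (2.0 * m + 1.0)
    term = s
    for i in range(1, 300):
        term *= 2.0 * T / (2.0 * m + 2.0 * i + 1.0)
        s += term
        if term < 1e-17 * s:
            break
    F[m] = s * expT
    for i in range(m - 1, -1, -1):
        F[i] = (2.0 * T * F[i + 1] + expT) / (2.0 * i + 1.0)


@njit(cache=True)
def _e_tab(imax, jmax, a, b, A, B, E):
    """Hermite expansion coefficients E[d, i, j, t] for i<=imax, j<=jmax."""
    p = a + b
    oo2p = 0.5 / p
    for d in range(3):
        for i in range(imax + 1):
            for j in range(jmax + 1):
                for t in range(i + j + 1):
                    E[d, i, j, t] = 0.0
        X = A[d] - B[d]
        PA = -b * X / p
        PB = a * X / p
        E[d, 0, 0, 0] = math.exp(-a * b * X * X / p)
        for i in range(imax):
            for t in range(i + 2):
                v = 0.0
                if t > 0:
                    v += oo2p * E[d, i, 0, t - 1]
                if t <= i:
                    v += PA * E[d, i, 0, t]
                if t + 1 <= i:
                    v += (t + 1.0) * E[d, i, 0, t + 1]
                E[d, i + 1, 0, t] = v
        for j in range(jmax):
            for i in range(imax + 1):
                for t in range(i + j + 2):
                    v = 0.0
                    if t > 0:
                        v += oo2p * E[d, i, j, t - 1]
                    if t <= i + j:
                        v += PB * E[d, i, j, t]
                    if t + 1 <= i + j:
                        v += (t + 1.0) * E[d, i, j, t + 1]
                    E[d, i, j + 1, t] = v


@njit(cache=True)
def _r_tensor(L, alpha, X, Y, Z, R4, F):
    """Hermite Coulomb integrals R[0, t, u, v] for t+u+v <= L."""
    T = alpha * (X * X + Y * Y + Z * Z)
    _boys(L, T, F)
    fac = 1.0
    for n in range(L + 1):
        R4[n, 0, 0, 0] = fac * F[n]
        fac *= -2.0 * alpha
    for t in range(L):
        for n in range(L - t):
            v = X * R4[n + 1, t, 0, 0]
            if t > 0:
                v += t * R4[n + 1, t - 1, 0, 0]
            R4[n, t + 1, 0, 0] = v
    for t in range(L + 1):
        for u in range(L - t):
            for n in range(L - t - u):
                v = Y * R4[n + 1, t, u, 0]
                if u > 0:
                    v += u * R4[n + 1, t, u - 1, 0]
                R4[n, t, u + 1, 0] = v
    for t in range(L + 1):
        for u in range(L + 1 - t):
            for v_ in range(L - t - u):
                for n in range(L - t - u - v_):
                    w = Z * R4[n + 1, t, u, v_]
                    if v_ > 0:
                        w += v_ * R4[n + 1, t, u, v_ - 1]
                    R4[n, t, u, v_ + 1] = w


@njit(cache=True)
def _s3(E, ax, ay, az, bx, by, bz):
    """Product of 1D overlap factors; zero for negative angular indices."""
    if ax < 0 or ay < 0 or az < 0 or bx < 0 or by < 0 or bz < 0:
        return 0.0
    return E[0, ax, bx, 0] * E[1, ay, by, 0] * E[2, az, bz, 0]


@njit(cache=True)
def _t3(E, ax, ay, az, bx, by, bz, b):
    """Kinetic-energy integral factor (missing the (pi/p)^{3/2} prefactor)."""
    if ax < 0 or ay < 0 or az < 0 or bx < 0 or by < 0 or bz < 0:
        return 0.0
    sx = E[0, ax, bx, 0]
    sy = E[1, ay, by, 0]
    sz = E[2, az, bz, 0]
    tx = b * (2.0 * bx + 1.0) * sx - 2.0 * b * b * E[0, ax, bx + 2, 0]
    if bx >= 2:
        tx -= 0.5 * bx * (bx - 1.0) * E[0, ax, bx - 2, 0]
    ty = b * (2.0 * by + 1.0) * sy - 2.0 * b * b * E[1, ay, by + 2, 0]
    if by >= 2:
        ty -= 0.5 * by * (by - 1.0) * E[1, ay, by - 2, 0]
    tz = b * (2.0 * bz + 1.0) * sz - 2.0 * b * b * E[2, az, bz + 2, 0]
    if bz >= 2:
        tz -= 0.5 * bz * (bz - 1.0) * E[2, az, bz - 2, 0]
    return tx * sy * sz + sx * ty * sz + sx * sy * tz


@njit(cache=True)
def _v3(E, R4, ax, ay, az, bx, by, bz):
    """Hermite contraction for one nuclear-attraction primitive integral."""
    if ax < 0 or ay < 0 or az < 0 or bx < 0 or by < 0 or bz < 0:
        return 0.0
    out = 0.0
    for t in range(ax + bx + 1):
        ex = E[0, ax, bx, t]
        for u in range(ay + by + 1):
            exy = ex * E[1, ay, by, u]
            for v in range(az + bz + 1):
                out += exy * E[2, az, bz, v] * R4[0, t, u, v]
    return out


@njit(cache=True)
def _eri6(E1, E2, R4, ax, ay, az, bx, by, bz, cx, cy, cz, dx, dy, dz):
    """Hermite contraction for one two-electron primitive integral."""
    if ax < 0 or ay < 0 or az < 0:
        return 0.0
    val = 0.0
    for t in range(ax + bx + 1):
        e1x = E1[0, ax, bx, t]
        for u in range(ay + by + 1):
            e1xy = e1x * E1[1, ay, by, u]
            for v in range(az + bz + 1):
                e1 = e1xy * E1[2, az, bz, v]
                if e1 == 0.0:
                    continue
                s = 0.0
                for tt in range(cx + dx + 1):
                    e2x = E2[0, cx, dx, tt]
                    for uu in range(cy + dy + 1):
                        e2xy = e2x * E2[1, cy, dy, uu]
                        for vv in range(cz + dz + 1):
                            term = (
                                e2xy * E2[2, cz, dz, vv]
                                * R4[0, t + tt, u + uu, v + vv]
                            )
                            if (tt + uu + vv) & 1:
                                s -= term
                            else:
                                s += term
                val += e1 * s
    return val


@njit(cache=True)
def _build_pair_tables(nsh, centers, ls, nprim, exps, coefs):
    """Hermite tables for all unique shell pairs (si >= sj).

    Tables are built to i <= l1+1 and j <= l2+2 so the same data serves
    overlap/kinetic integrals, ket increments and bra gradient increments.
    """
    npair = nsh * (nsh + 1) // 2
    MP = exps.shape[1]
    pE = np.zeros((npair, MP, MP, 3, MI, MJ, MT))
    pP = np.zeros((npair, MP, MP, 3))
    pp = np.zeros((npair, MP, MP))
    pc = np.zeros((npair, MP, MP))
    pk = np.zeros((npair, MP, MP))  # Gaussian-product magnitude for screening
    for si in range(nsh):
        for sj in range(si + 1):
            pidx = si * (si + 1) // 2 + sj
            l1 = ls[si]
            l2 = ls[sj]
            for kp in range(nprim[si]):
                a = exps[si, kp]
                for lp in range(nprim[sj]):
                    b = exps[sj, lp]
                    p = a + b
                    pp[pidx, kp, lp] = p
                    for d in range(3):
                        pP[pidx, kp, lp, d] = (
                            a * centers[si, d] + b * centers[sj, d]
                        ) / p
                    pc[pidx, kp, lp] = coefs[si, kp] * coefs[sj, lp]
                    _e_tab(
                        l1 + 1, l2 + 2, a, b,
                        centers[si], centers[sj], pE[pidx, kp, lp],
                    )
                    pk[pidx, kp, lp] = (
                        pE[pidx, kp, lp, 0, 0, 0, 0]
                        * pE[pidx, kp, lp, 1, 0, 0, 0]
                        * pE[pidx, kp, lp, 2, 0, 0, 0]
                    )
    return pE, pP, pp, pc, pk


@njit(cache=True)
def _schwarz_pairs(nsh, ls, nprim, pair_i, pair_j, pE, pP, pp, pc):
    """Q[pair] = sqrt(max_comp (ab|ab)) Cauchy-Schwarz bounds."""
    npair = nsh * (nsh + 1) // 2
    Q = np.zeros(npair)
    R4 = np.zeros((LMAXR, LMAXR, LMAXR, LMAXR))
    F = np.zeros(LMAXR)
    pi52 = 2.0 * math.pi ** 2.5
    for pidx in range(npair):
        si = pair_i[pidx]
        sj = pair_j[pidx]
        l1 = ls[si]
        l2 = ls[sj]
        n1 = _ncomp(l1)
        n2 = _ncomp(l2)
        o1 = _COFF[l1]
        o2 = _COFF[l2]
        L = 2 * (l1 + l2)
        best = 0.0
        for ca in range(n1):
            ax = _CLX[o1 + ca]
            ay = _CLY[o1 + ca]
            az = _CLZ[o1 + ca]
            for cb in range(n2):
                bx = _CLX[o2 + cb]
                by = _CLY[o2 + cb]
                bz = _CLZ[o2 + cb]
                val = 0.0
                for kp in range(nprim[si]):
                    for lp in range(nprim[sj]):
                        E1 = pE[pidx, kp, lp]
                        p = pp[pidx, kp, lp]
                        c1 = pc[pidx, kp, lp]
                        for mp in range(nprim[si]):
                            for np_ in range(nprim[sj]):
                                E2 = pE[pidx, mp, np_]
                                q = pp[pidx, mp, np_]
                                alpha = p * q / (p + q)
                                pref = (
                                    pi52 / (p * q * math.sqrt(p + q))
                                    * c1 * pc[pidx, mp, np_]
                                )
                                _r_tensor(
                                    L, alpha,
                                    pP[pidx, kp, lp, 0] - pP[pidx, mp, np_, 0],
                                    pP[pidx, kp, lp, 1] - pP[pidx, mp, np_, 1],
                                    pP[pidx, kp, lp, 2] - pP[pidx, mp, np_, 2],
                                    R4, F,
                                )
                                val += pref * _eri6(
                                    E1, E2, R4,
                                    ax, ay, az, bx, by, bz,
                                    ax, ay, az, bx, by, bz,
                                )
                if val > best:
                    best = val
        Q[pidx] = math.sqrt(abs(best))
    return Q


@njit(cache=True)
def _overlap_kinetic(nsh, ls, nprim, exps, ao, pE, pp, pc, nao):
    S = np.zeros((nao, nao))
    T = np.zeros((nao, nao))
    for si in range(nsh):
        for sj in range(si + 1):
            pidx = si * (si + 1) // 2 + sj
            l1 = ls[si]
            l2 = ls[sj]
            n1 = _ncomp(l1)
            n2 = _ncomp(l2)
            o1 = _COFF[l1]
            o2 = _COFF[l2]
            for kp in range(nprim[si]):
                for lp in range(nprim[sj]):
                    E = pE[pidx, kp, lp]
                    b = exps[sj, lp]
                    pref = pc[pidx, kp, lp] * (
                        math.pi / pp[pidx, kp, lp]
                    ) ** 1.5
                    for ca in range(n1):
                        ax = _CLX[o1 + ca]
                        ay = _CLY[o1 + ca]
                        az = _CLZ[o1 + ca]
                        i0 = ao[si] + ca
                        for cb in range(n2):
                            bx = _CLX[o2 + cb]
                            by = _CLY[o2 + cb]
                            bz = _CLZ[o2 + cb]
                            j0 = ao[sj] + cb
                            S[i0, j0] += pref * _s3(E, ax, ay, az, bx, by, bz)
                            T[i0, j0] += pref * _t3(E, ax, ay, az, bx, by, bz, b)
    for i in range(nao):
        for j in range(i):
            S[j, i] = S[i, j]
            T[j, i] = T[i, j]
    return S, T


@njit(cache=True)
def _nuclear_attraction(
    nsh, ls, nprim, exps, ao, pE, pP, pp, pc, nao, nuc_xyz, nuc_Z
):
    V = np.zeros((nao, nao))
    R4 = np.zeros((LMAXR, LMAXR, LMAXR, LMAXR))
    F = np.zeros(LMAXR)
    nnuc = nuc_Z.shape[0]
    for si in range(nsh):
        for sj in range(si + 1):
            pidx = si * (si + 1) // 2 + sj
            l1 = ls[si]
            l2 = ls[sj]
            n1 = _ncomp(l1)
            n2 = _ncomp(l2)
            o1 = _COFF[l1]
            o2 = _COFF[l2]
            L = l1 + l2
            for kp in range(nprim[si]):
                for lp in range(nprim[sj]):
                    E = pE[pidx, kp, lp]
                    p = pp[pidx, kp, lp]
                    pref = pc[pidx, kp, lp] * 2.0 * math.pi / p
                    for c in range(nnuc):
                        Z = nuc_Z[c]
                        if Z == 0.0:
                            continue
                        _r_tensor(
                            L, p,
                            pP[pidx, kp, lp, 0] - nuc_xyz[c, 0],
                            pP[pidx, kp, lp, 1] - nuc_xyz[c, 1],
                            pP[pidx, kp, lp, 2] - nuc_xyz[c, 2],
                            R4, F,
                        )
                        for ca in range(n1):
                            ax = _CLX[o1 + ca]
                            ay = _CLY[o1 + ca]
                            az = _CLZ[o1 + ca]
                            i0 = ao[si] + ca
                            for cb in range(n2):
                                bx = _CLX[o2 + cb]
                                by = _CLY[o2 + cb]
                                bz = _CLZ[o2 + cb]
                                j0 = ao[sj] + cb
                                V[i0, j0] -= Z * pref * _v3(
                                    E, R4, ax, ay, az, bx, by, bz
                                )
    for i in range(nao):
        for j in range(i):
            V[j, i] = V[i, j]
    return V


@njit(cache=True)
def _ket_hermite(E2, R4, K, tmax, n3, n4, o3, o4):
    """Contract ket Hermite coefficients with R into K[t, u, v, ketcomp].

    K absorbs the (-1)^{T+U+V} ket phase, leaving the caller a pure
    bra-side Hermite sum per target component.
    """
    for cc in range(n3):
        cx = _CLX[o3 + cc]
        cy = _CLY[o3 + cc]
        cz = _CLZ[o3 + cc]
        for cd in range(n4):
            dx = _CLX[o4 + cd]
            dy = _CLY[o4 + cd]
            dz = _CLZ[o4 + cd]
            kc = cc * n4 + cd
            for t in range(tmax + 1):
                for u in range(tmax + 1 - t):
                    for v in range(tmax + 1 - t - u):
                        s = 0.0
                        for tt in range(cx + dx + 1):
                            e2x = E2[0, cx, dx, tt]
                            for uu in range(cy + dy + 1):
                                e2xy = e2x * E2[1, cy, dy, uu]
                                for vv in range(cz + dz + 1):
                                    term = (
                                        e2xy * E2[2, cz, dz, vv]
                                        * R4[0, t + tt, u + uu, v + vv]
                                    )
                                    if (tt + uu + vv) & 1:
                                        s -= term
                                    else:
                                        s += term
                        K[kc, t, u, v] = s


@njit(cache=True)
def _eri_tensor(
    nsh, ls, nprim, ao, pair_i, pair_j, pE, pP, pp, pc, pK, pQ, nao
):
    eri = np.zeros((nao, nao, nao, nao))
    R4 = np.zeros((LMAXR, LMAXR, LMAXR, LMAXR))
    F = np.zeros(LMAXR)
    K = np.zeros((9, 5, 5, 5))
    npair = nsh * (nsh + 1) // 2
    pi52 = 2.0 * math.pi ** 2.5
    for pb in range(npair):
        si = pair_i[pb]
        sj = pair_j[pb]
        l1 = ls[si]
        l2 = ls[sj]
        n1 = _ncomp(l1)
        n2 = _ncomp(l2)
        o1 = _COFF[l1]
        o2 = _COFF[l2]
        for pk in range(pb + 1):
            if pQ[pb] * pQ[pk] < 1e-14:
                continue
            sk = pair_i[pk]
            sl = pair_j[pk]
            l3 = ls[sk]
            l4 = ls[sl]
            n3 = _ncomp(l3)
            n4 = _ncomp(l4)
            o3 = _COFF[l3]
            o4 = _COFF[l4]
            L = l1 + l2 + l3 + l4
            tmax = l1 + l2
            block = np.zeros((n1, n2, n3, n4))
            for kp in range(nprim[si]):
                for lp in range(nprim[sj]):
                    E1 = pE[pb, kp, lp]
                    p = pp[pb, kp, lp]
                    c1 = pc[pb, kp, lp]
                    for mp in range(nprim[sk]):
                        for np_ in range(nprim[sl]):
                            E2 = pE[pk, mp, np_]
                            q = pp[pk, mp, np_]
                            alpha = p * q / (p + q)
                            pref = (
                                pi52 / (p * q * math.sqrt(p + q))
                                * c1 * pc[pk, mp, np_]
                            )
                            if (
                                abs(pref) * pK[pb, kp, lp] * pK[pk, mp, np_]
                                < 1e-16
                            ):
                                continue
                            _r_tensor(
                                L, alpha,
                                pP[pb, kp, lp, 0] - pP[pk, mp, np_, 0],
                                pP[pb, kp, lp, 1] - pP[pk, mp, np_, 1],
                                pP[pb, kp, lp, 2] - pP[pk, mp, np_, 2],
                                R4, F,
                            )
                            _ket_hermite(E2, R4, K, tmax, n3, n4, o3, o4)
                            for ca in range(n1):
                                ax = _CLX[o1 + ca]
                                ay = _CLY[o1 + ca]
                                az = _CLZ[o1 + ca]
                                for cb in range(n2):
                                    bx = _CLX[o2 + cb]
                                    by = _CLY[o2 + cb]
                                    bz = _CLZ[o2 + cb]
                                    for cc in range(n3):
                                        for cd in range(n4):
                                            kc = cc * n4 + cd
                                            s = 0.0
                                            for t in range(ax + bx + 1):
                                                e1x = E1[0, ax, bx, t]
                                                for u in range(ay + by + 1):
                                                    e1xy = e1x * E1[1, ay, by, u]
                                                    for v in range(az + bz + 1):
                                                        s += (
                                                            e1xy
                                                            * E1[2, az, bz, v]
                                                            * K[kc, t, u, v]
                                                        )
                                            block[ca, cb, cc, cd] += pref * s
            for ca in range(n1):
                i0 = ao[si] + ca
                for cb in range(n2):
                    j0 = ao[sj] + cb
                    for cc in range(n3):
                        k0 = ao[sk] + cc
                        for cd in range(n4):
                            l0 = ao[sl] + cd
                            v = block[ca, cb, cc, cd]
                            eri[i0, j0, k0, l0] = v
                            eri[j0, i0, k0, l0] = v
                            eri[i0, j0, l0, k0] = v
                            eri[j0, i0, l0, k0] = v
                            eri[k0, l0, i0, j0] = v
                            eri[l0, k0, i0, j0] = v
                            eri[k0, l0, j0, i0] = v
                            eri[l0, k0, j0, i0] = v
    return eri


@njit(cache=True)
def _grad_one_electron(
    nsh, shell_atom, centers, ls, nprim, exps, ao,
    pE, pP, pp, pc, nuc_xyz, nuc_Z, P, W, grad
):
    """Accumulate d/dR [ Tr(P(T+V)) - Tr(W S) ] into grad (hartree/bohr)."""
    R4 = np.zeros((LMAXR, LMAXR, LMAXR, LMAXR))
    F = np.zeros(LMAXR)
    nnuc = nuc_Z.shape[0]
    dV1 = np.zeros(3)
    dV2 = np.zeros(3)
    for si in range(nsh):
        for sj in range(si + 1):
            pidx = si * (si + 1) // 2 + sj
            atom_a = shell_atom[si]
            atom_b = shell_atom[sj]
            l1 = ls[si]
            l2 = ls[sj]
            n1 = _ncomp(l1)
            n2 = _ncomp(l2)
            o1 = _COFF[l1]
            o2 = _COFF[l2]
            fac = 1.0 if si == sj else 2.0
            L = l1 + l2 + 1
            for kp in range(nprim[si]):
                a = exps[si, kp]
                for lp in range(nprim[sj]):
                    b = exps[sj, lp]
                    E = pE[pidx, kp, lp]
                    p = pp[pidx, kp, lp]
                    sqp = (math.pi / p) ** 1.5
                    cpre = pc[pidx, kp, lp]
                    for ca in range(n1):
                        ia = np.empty(3, dtype=np.int64)
                        ia[0] = _CLX[o1 + ca]
                        ia[1] = _CLY[o1 + ca]
                        ia[2] = _CLZ[o1 + ca]
                        i0 = ao[si] + ca
                        for cb in range(n2):
                            jb = np.empty(3, dtype=np.int64)
                            jb[0] = _CLX[o2 + cb]
                            jb[1] = _CLY[o2 + cb]
                            jb[2] = _CLZ[o2 + cb]
                            j0 = ao[sj] + cb
                            pv = P[i0, j0]
                            wv = W[i0, j0]
                            if si == sj and ca == cb:
                                # diagonal: dS = dT = 0 by symmetry, and the
                                # nuclear term keeps only the operator part
                                pass
                            # overlap & kinetic derivatives wrt bra center;
                            # ket center by translational invariance
                            for d in range(3):
                                axp = ia[0] + (1 if d == 0 else 0)
                                ayp = ia[1] + (1 if d == 1 else 0)
                                azp = ia[2] + (1 if d == 2 else 0)
                                axm = ia[0] - (1 if d == 0 else 0)
                                aym = ia[1] - (1 if d == 1 else 0)
                                azm = ia[2] - (1 if d == 2 else 0)
                                idd = ia[d]
                                dS = 2.0 * a * _s3(
                                    E, axp, ayp, azp, jb[0], jb[1], jb[2]
                                )
                                dT = 2.0 * a * _t3(
                                    E, axp, ayp, azp, jb[0], jb[1], jb[2], b
                                )
                                if idd > 0:
                                    dS -= idd * _s3(
                                        E, axm, aym, azm, jb[0], jb[1], jb[2]
                                    )
                                    dT -= idd * _t3(
                                        E, axm, aym, azm, jb[0], jb[1], jb[2], b
                                    )
                                dS *= cpre * sqp
                                dT *= cpre * sqp
                                val = fac * (pv * dT - wv * dS)
                                grad[atom_a, d] += val
                                grad[atom_b, d] -= val
                            # nuclear attraction: bra, ket and operator terms
                            for c in range(nnuc):
                                Z = nuc_Z[c]
                                if Z == 0.0:
                                    continue
                                _r_tensor(
                                    L, p,
                                    pP[pidx, kp, lp, 0] - nuc_xyz[c, 0],
                                    pP[pidx, kp, lp, 1] - nuc_xyz[c, 1],
                                    pP[pidx, kp, lp, 2] - nuc_xyz[c, 2],
                                    R4, F,
                                )
                                vpre = -Z * cpre * 2.0 * math.pi / p
                                for d in range(3):
                                    axp = ia[0] + (1 if d == 0 else 0)
                                    ayp = ia[1] + (1 if d == 1 else 0)
                                    azp = ia[2] + (1 if d == 2 else 0)
                                    axm = ia[0] - (1 if d == 0 else 0)
                                    aym = ia[1] - (1 if d == 1 else 0)
                                    azm = ia[2] - (1 if d == 2 else 0)
                                    bxp = jb[0] + (1 if d == 0 else 0)
                                    byp = jb[1] + (1 if d == 1 else 0)
                                    bzp = jb[2] + (1 if d == 2 else 0)
                                    bxm = jb[0] - (1 if d == 0 else 0)
                                    bym = jb[1] - (1 if d == 1 else 0)
                                    bzm = jb[2] - (1 if d == 2 else 0)
                                    d1 = 2.0 * a * _v3(
                                        E, R4, axp, ayp, azp,
                                        jb[0], jb[1], jb[2],
                                    )
                                    if ia[d] > 0:
                                        d1 -= ia[d] * _v3(
                                            E, R4, axm, aym, azm,
                                            jb[0], jb[1], jb[2],
                                        )
                                    d2 = 2.0 * b * _v3(
                                        E, R4, ia[0], ia[1], ia[2],
                                        bxp, byp, bzp,
                                    )
                                    if jb[d] > 0:
                                        d2 -= jb[d] * _v3(
                                            E, R4, ia[0], ia[1], ia[2],
                                            bxm, bym, bzm,
                                        )
                                    dV1[d] = vpre * d1
                                    dV2[d] = vpre * d2
                                    gval = fac * pv
                                    grad[atom_a, d] += gval * dV1[d]
                                    grad[atom_b, d] += gval * dV2[d]
                                    grad[c, d] -= gval * (dV1[d] + dV2[d])


@njit(cache=True, fastmath=True)
def _grad_eri_contract(
    nsh, shell_atom, centers, ls, nprim, exps, coefs, ao,
    pair_i, pair_j, pE, pP, pp, pc, pK, pQ, P, skip, grad
):
    """Accumulate the two-electron RHF gradient into grad (hartree/bohr).

    Runs over unique bra shell pairs and unique ket pairs; per quartet the
    derivatives with respect to both bra centers are formed by angular
    increments -- index relabelling of the 8-fold symmetric integrals makes
    this sum exactly the full two-electron gradient.  Quartets are screened
    by Cauchy-Schwarz bounds weighted with shell-block density maxima.
    """
    MP = exps.shape[1]
    R4 = np.zeros((LMAXR, LMAXR, LMAXR, LMAXR))
    F = np.zeros(LMAXR)
    Eb = np.zeros((MP, MP, 3, MI, MJ, MT))
    K = np.zeros((9, 5, 5, 5))
    BA = np.zeros((3, 5, 5, 5))
    BB = np.zeros((3, 5, 5, 5))
    npair = nsh * (nsh + 1) // 2
    pi52 = 2.0 * math.pi ** 2.5
    # per-shell-block density maxima for density-weighted screening
    shellPmax = np.zeros((nsh, nsh))
    for s1 in range(nsh):
        a1 = ao[s1]
        n1_ = _ncomp(ls[s1])
        for s2 in range(nsh):
            a2 = ao[s2]
            n2_ = _ncomp(ls[s2])
            m = 0.0
            for i in range(a1, a1 + n1_):
                for j in range(a2, a2 + n2_):
                    if abs(P[i, j]) > m:
                        m = abs(P[i, j])
            shellPmax[s1, s2] = m
    for si in range(nsh):
        atom_a = shell_atom[si]
        l1 = ls[si]
        n1 = _ncomp(l1)
        o1 = _COFF[l1]
        for sj in range(si + 1):
            atom_b = shell_atom[sj]
            l2 = ls[sj]
            n2 = _ncomp(l2)
            o2 = _COFF[l2]
            pb = si * (si + 1) // 2 + sj
            both = si != sj
            need_a = not skip[atom_a]
            need_b = both and not skip[atom_b]
            if not (need_a or need_b):
                continue
            for kp in range(nprim[si]):
                for lp in range(nprim[sj]):
                    _e_tab(
                        l1 + 1, l2 + 1, exps[si, kp], exps[sj, lp],
                        centers[si], centers[sj], Eb[kp, lp],
                    )
            for pk in range(npair):
                sk = pair_i[pk]
                sl = pair_j[pk]
                dbound = (
                    2.0 * shellPmax[si, sj] * shellPmax[sk, sl]
                    + shellPmax[si, sk] * shellPmax[sj, sl]
                    + shellPmax[si, sl] * shellPmax[sj, sk]
                )
                if pQ[pb] * pQ[pk] * dbound < 1e-10:
                    continue
                l3 = ls[sk]
                l4 = ls[sl]
                n3 = _ncomp(l3)
                n4 = _ncomp(l4)
                o3 = _COFF[l3]
                o4 = _COFF[l4]
                kfac = 1.0 if sk == sl else 2.0
                L = l1 + 1 + l2 + l3 + l4
                tmax = l1 + 1 + l2
                for kp in range(nprim[si]):
                    a = exps[si, kp]
                    for lp in range(nprim[sj]):
                        b = exps[sj, lp]
                        p = a + b
                        c1 = coefs[si, kp] * coefs[sj, lp]
                        Px = (a * centers[si, 0] + b * centers[sj, 0]) / p
                        Py = (a * centers[si, 1] + b * centers[sj, 1]) / p
                        Pz = (a * centers[si, 2] + b * centers[sj, 2]) / p
                        E1 = Eb[kp, lp]
                        kb_bra = (
                            E1[0, 0, 0, 0] * E1[1, 0, 0, 0] * E1[2, 0, 0, 0]
                        )
                        for mp in range(nprim[sk]):
                            for np_ in range(nprim[sl]):
                                E2 = pE[pk, mp, np_]
                                q = pp[pk, mp, np_]
                                alpha = p * q / (p + q)
                                pref = (
                                    pi52 / (p * q * math.sqrt(p + q))
                                    * c1 * pc[pk, mp, np_]
                                )
                                if (
                                    abs(pref) * kb_bra * pK[pk, mp, np_]
                                    * dbound < 1e-13
                                ):
                                    continue
                                _r_tensor(
                                    L, alpha,
                                    Px - pP[pk, mp, np_, 0],
                                    Py - pP[pk, mp, np_, 1],
                                    Pz - pP[pk, mp, np_, 2],
                                    R4, F,
                                )
                                _ket_hermite(E2, R4, K, tmax, n3, n4, o3, o4)
                                for ca in range(n1):
                                    ax = _CLX[o1 + ca]
                                    ay = _CLY[o1 + ca]
                                    az = _CLZ[o1 + ca]
                                    i0 = ao[si] + ca
                                    for cb in range(n2):
                                        bx = _CLX[o2 + cb]
                                        by = _CLY[o2 + cb]
                                        bz = _CLZ[o2 + cb]
                                        j0 = ao[sj] + cb
                                        pij = P[i0, j0]
                                        # bra Hermite products, one array per
                                        # derivative center x dimension; they
                                        # do not depend on the ket component
                                        ntx = ax + bx + 2
                                        ntu = ay + by + 2
                                        ntv = az + bz + 2
                                        for t in range(ntx):
                                            ex = E1[0, ax, bx, t] if t <= ax + bx else 0.0
                                            gx = 2.0 * a * E1[0, ax + 1, bx, t]
                                            hx = 2.0 * b * E1[0, ax, bx + 1, t]
                                            if ax > 0 and t <= ax - 1 + bx:
                                                gx -= ax * E1[0, ax - 1, bx, t]
                                            if bx > 0 and t <= ax + bx - 1:
                                                hx -= bx * E1[0, ax, bx - 1, t]
                                            for u in range(min(ntu, tmax + 1 - t)):
                                                ey = E1[1, ay, by, u] if u <= ay + by else 0.0
                                                gy = 2.0 * a * E1[1, ay + 1, by, u]
                                                hy = 2.0 * b * E1[1, ay, by + 1, u]
                                                if ay > 0 and u <= ay - 1 + by:
                                                    gy -= ay * E1[1, ay - 1, by, u]
                                                if by > 0 and u <= ay + by - 1:
                                                    hy -= by * E1[1, ay, by - 1, u]
                                                for v in range(
                                                    min(ntv, tmax + 1 - t - u)
                                                ):
                                                    ez = E1[2, az, bz, v] if v <= az + bz else 0.0
                                                    gz = 2.0 * a * E1[2, az + 1, bz, v]
                                                    hz = 2.0 * b * E1[2, az, bz + 1, v]
                                                    if az > 0 and v <= az - 1 + bz:
                                                        gz -= az * E1[2, az - 1, bz, v]
                                                    if bz > 0 and v <= az + bz - 1:
                                                        hz -= bz * E1[2, az, bz - 1, v]
                                                    BA[0, t, u, v] = gx * ey * ez
                                                    BA[1, t, u, v] = ex * gy * ez
                                                    BA[2, t, u, v] = ex * ey * gz
                                                    BB[0, t, u, v] = hx * ey * ez
                                                    BB[1, t, u, v] = ex * hy * ez
                                                    BB[2, t, u, v] = ex * ey * hz
                                        for cc in range(n3):
                                            k0 = ao[sk] + cc
                                            for cd in range(n4):
                                                l0 = ao[sl] + cd
                                                kc = cc * n4 + cd
                                                coef = pref * (
                                                    kfac * 2.0 * pij
                                                    * P[k0, l0]
                                                    - 0.5 * kfac * (
                                                        P[i0, k0] * P[j0, l0]
                                                        + P[i0, l0] * P[j0, k0]
                                                    )
                                                )
                                                if abs(coef) < 1e-15:
                                                    continue
                                                sax = 0.0
                                                say = 0.0
                                                saz = 0.0
                                                sbx = 0.0
                                                sby = 0.0
                                                sbz = 0.0
                                                for t in range(ntx):
                                                    for u in range(
                                                        min(ntu, tmax + 1 - t)
                                                    ):
                                                        for v in range(
                                                            min(ntv, tmax + 1 - t - u)
                                                        ):
                                                            kk = K[kc, t, u, v]
                                                            if kk == 0.0:
                                                                continue
                                                            sax += BA[0, t, u, v] * kk
                                                            say += BA[1, t, u, v] * kk
                                                            saz += BA[2, t, u, v] * kk
                                                            sbx += BB[0, t, u, v] * kk
                                                            sby += BB[1, t, u, v] * kk
                                                            sbz += BB[2, t, u, v] * kk
                                                grad[atom_a, 0] += coef * sax
                                                grad[atom_a, 1] += coef * say
                                                grad[atom_a, 2] += coef * saz
                                                if both:
                                                    grad[atom_b, 0] += coef * sbx
                                                    grad[atom_b, 1] += coef * sby
                                                    grad[atom_b, 2] += coef * sbz


class IntegralContext:
    """All molecular integrals for one geometry and basis."""

    def __init__(self, basis):
        self.basis = basis
        nsh = basis.nshells
        pi_idx = np.empty(nsh * (nsh + 1) // 2, dtype=np.int64)
        pj_idx = np.empty_like(pi_idx)
        for si in range(nsh):
            for sj in range(si + 1):
                pidx = si * (si + 1) // 2 + sj
                pi_idx[pidx] = si
                pj_idx[pidx] = sj
        self.pair_i = pi_idx
        self.pair_j = pj_idx
        self.pE, self.pP, self.pp, self.pc, self.pKs = _build_pair_tables(
            nsh, basis.shell_center, basis.shell_l, basis.shell_nprim,
            basis.shell_exp, basis.shell_coef,
        )
        self.pQ = _schwarz_pairs(
            nsh, basis.shell_l, basis.shell_nprim,
            self.pair_i, self.pair_j, self.pE, self.pP, self.pp, self.pc,
        )

    def overlap_kinetic(self):
        b = self.basis
        return _overlap_kinetic(
            b.nshells, b.shell_l, b.shell_nprim, b.shell_exp, b.shell_ao,
            self.pE, self.pp, self.pc, b.nao,
        )

    def nuclear_attraction(self, nuc_xyz_bohr, nuc_Z):
        b = self.basis
        return _nuclear_attraction(
            b.nshells, b.shell_l, b.shell_nprim, b.shell_exp, b.shell_ao,
            self.pE, self.pP, self.pp, self.pc, b.nao,
            np.ascontiguousarray(nuc_xyz_bohr, dtype=np.float64),
            np.asarray(nuc_Z, dtype=np.float64),
        )

    def eri(self):
        b = self.basis
        return _eri_tensor(
            b.nshells, b.shell_l, b.shell_nprim, b.shell_ao,
            self.pair_i, self.pair_j, self.pE, self.pP, self.pp, self.pc,
            self.pKs, self.pQ, b.nao,
        )

    def gradient(self, nuc_xyz_bohr, nuc_Z, P, W, skip=None):
        """Density-contracted derivative of the electronic energy.

        Returns d/dR [ Tr(P h) + E_2e[P] - Tr(W S) ] in hartree/bohr with
        one row per atom; nuclear repulsion is added by the caller.
        ``skip`` marks atoms whose force is not needed (rows left
        incomplete); used by symmetry- and pin-aware optimizations.
        """
        b = self.basis
        natom = len(nuc_Z)
        if skip is None:
            skip = np.zeros(natom, dtype=np.bool_)
        grad = np.zeros((natom, 3))
        _grad_one_electron(
            b.nshells, b.shell_atom, b.shell_center, b.shell_l,
            b.shell_nprim, b.shell_exp, b.shell_ao,
            self.pE, self.pP, self.pp, self.pc,
            np.ascontiguousarray(nuc_xyz_bohr, dtype=np.float64),
            np.asarray(nuc_Z, dtype=np.float64),
            np.ascontiguousarray(P), np.ascontiguousarray(W), grad,
        )
        _grad_eri_contract(
            b.nshells, b.shell_atom, b.shell_center, b.shell_l,
            b.shell_nprim, b.shell_exp, b.shell_coef, b.shell_ao,
            self.pair_i, self.pair_j, self.pE, self.pP, self.pp, self.pc,
            self.pKs, self.pQ, np.ascontiguousarray(P),
            np.ascontiguousarray(skip, dtype=np.bool_), grad,
        )
        return grad
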