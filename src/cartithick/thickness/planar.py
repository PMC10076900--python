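"""2D slice-wise methods: centerline normals (2D-CN) and surface normals (2D-SN).

Both methods operate on sagittal slices (fixed y) of the segmented
cartilage, fitting third-order polynomials z(x) in in-plane physical units.
Degree three keeps the fits free of edge oscillations while accommodating
the at-most-two inflection points seen in cartilage cross-sections.

2D-CN fits one cubic through all cartilage pixels of the slice (the
centerline) and, per pixel column, marches the centerline normal in both
directions at 0.1-pixel resolution to the last cartilage pixel crossed
before exiting on each side; the thickness is the distance between the two
outline intersection points, allocated by the more distal one.

2D-SN fits separate cubics to the distal and proximal outline pixels (the
per-column surface extremes), and intersects the normal of the distal fit
at (x, fd(x)) with the proximal cubic by exact cubic root finding; the
thickness is the distance from (x, fd(x)) to the chosen intersection,
allocated by (x, fd(x)) and the slice coordinate y.

Femoral slices are split into an anterior+central and a posterior portion
(cubics cannot represent the hook-shaped posterior outline); the posterior
portion is rotated 90 degrees in-plane — mirroring the 3D treatment — and
each portion is fitted separately.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import MethodFailureError
from ..regions import SubregionLabeling
from ..volume_io import VoxelPointSet
from .base import MAX_PLAUSIBLE_THICKNESS_MM, ThicknessMap, apply_thickness_cap

_POSTERIOR = ("pLF", "pMF")


@dataclass(frozen=True)
class SlicePolynomialFit:
    """A degree-3 polynomial z(x) fitted within one sagittal slice."""

    coeffs: np.ndarray  # highest power first, length 4
    domain: tuple[float, float]
    role: str  # centerline | distal | proximal

    def __call__(self, x, *, margin: float = 0.0):
        x = np.asarray(x, dtype=float)
        lo, hi = self.domain
        if np.any((x < lo - margin - 1e-9) | (x > hi + margin + 1e-9)):
            raise ValueError("evaluation outside fit domain")
        return np.polyval(self.coeffs, x)

    def deriv(self, x):
        return np.polyval(np.polyder(self.coeffs), x)


class SliceSkipped(Exception):
    """Raised internally when a slice has too few columns to fit."""


def fit_slice_polynomial(x: np.ndarray, z: np.ndarray, role: str) -> SlicePolynomialFit:
    """Least-squares cubic z(x); requires >= 5 distinct x positions."""
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    if len(np.unique(x)) < 5:
        raise SliceSkipped(f"{role}: fewer than 5 distinct x positions")
    V = np.vander(x, 4)
    coeffs, _res, rank, _sv = np.linalg.lstsq(V, z, rcond=None)
    if rank < 4:
        raise SliceSkipped(f"{role}: rank-deficient fit")
    return SlicePolynomialFit(
        coeffs=coeffs, domain=(float(x.min()), float(x.max())), role=role
    )


def _slice_groups(points: VoxelPointSet, labeling: SubregionLabeling, structure: str):
    """Yield (j, swapped, pixels) per sagittal slice and fitting group.

    ``pixels`` is an (n, 2) integer array of (column, height) indices in the
    working frame; the posterior femoral group is swapped in-plane so its
    outline is single-valued over the working column axis.
    """
    sub, _ = labeling.assign(points.coords, structure=structure)
    if structure == "femur":
        post = np.isin(sub, _POSTERIOR)
        groups = [(~post, False), (post, True)]
    else:
        groups = [(np.ones(len(points), bool), False)]
    for mask, swapped in groups:
        idx = points.indices[mask]
        if len(idx) == 0:
            continue
        for j in np.unique(idx[:, 1]):
            pix = idx[idx[:, 1] == j]
            ij = pix[:, [2, 0]] if swapped else pix[:, [0, 2]]
            yield int(j), swapped, ij


def _working_spacing(spacing, swapped):
    sx, _sy, sz = spacing
    return (sz, sx) if swapped else (sx, sz)


def _to_original(xw, zw, swapped):
    return (zw, xw) if swapped else (xw, zw)


def _entry_end(occ: np.ndarray):
    """Per row of an occupancy matrix: first True, and last True before the
    first subsequent False (run end).  Returns (has, entry, end) arrays."""
    n, m = occ.shape
    has = occ.any(axis=1)
    entry = np.argmax(occ, axis=1)
    idxs = np.arange(m)
    after = (idxs[None, :] > entry[:, None]) & ~occ
    has_exit = after.any(axis=1)
    end = np.where(has_exit, np.argmax(after, axis=1) - 1, m - 1)
    return has, entry, end


def thickness_centerline_2d(
    points: VoxelPointSet,
    labeling: SubregionLabeling,
    structure: str,
    *,
    step_frac: float = 0.1,
    max_thickness: float = MAX_PLAUSIBLE_THICKNESS_MM,
) -> ThicknessMap:
    counts: dict = {"slices_skipped": 0, "failed_normals": 0}
    sy = points.spacing[1]
    origins, values = [], []
    for j, swapped, ij in _slice_groups(points, labeling, structure):
        wsx, wsz = _working_spacing(points.spacing, swapped)
        xs = ij[:, 0] * wsx
        zs = ij[:, 1] * wsz
        try:
            fit = fit_slice_polynomial(xs, zs, "centerline")
        except SliceSkipped:
            counts["slices_skipped"] += 1
            continue
        occ = np.zeros((ij[:, 0].max() + 1, ij[:, 1].max() + 1), dtype=bool)
        occ[ij[:, 0], ij[:, 1]] = True

        cols = np.unique(ij[:, 0])
        x0 = cols * wsx
        z0 = fit(x0)
        d = fit.deriv(x0)
        nrm = np.sqrt(1.0 + d**2)
        n = np.column_stack([-d / nrm, 1.0 / nrm])  # unit normal, sign arbitrary
        step = step_frac * min(wsx, wsz)
        s = np.arange(0.0, max_thickness + step, step)

        def occupancy(px, pz):
            i = np.rint(px / wsx).astype(int)
            k = np.rint(pz / wsz).astype(int)
            ok = (i >= 0) & (i < occ.shape[0]) & (k >= 0) & (k < occ.shape[1])
            out = np.zeros(px.shape, dtype=bool)
            out[ok] = occ[i[ok], k[ok]]
            return out

        p0 = np.column_stack([x0, z0])
        occ_pos = occupancy(
            p0[:, 0, None] + s[None, :] * n[:, 0, None],
            p0[:, 1, None] + s[None, :] * n[:, 1, None],
        )
        occ_neg = occupancy(
            p0[:, 0, None] - s[None, :] * n[:, 0, None],
            p0[:, 1, None] - s[None, :] * n[:, 1, None],
        )
        has_p, ent_p, end_p = _entry_end(occ_pos)
        has_n, ent_n, end_n = _entry_end(occ_neg)
        inside0 = occ_pos[:, 0]

        for r in range(len(x0)):
            if inside0[r]:
                # centerline point inside: endpoints on both sides
                ep = p0[r] + s[end_p[r]] * n[r]
                en = p0[r] - s[end_n[r]] * n[r]
                val = s[end_p[r]] + s[end_n[r]]
            else:
                cand = []
                if has_p[r]:
                    cand.append((ent_p[r], +1, ent_p[r], end_p[r]))
                if has_n[r]:
                    cand.append((ent_n[r], -1, ent_n[r], end_n[r]))
                if not cand:
                    counts["failed_normals"] += 1
                    continue
                cand.sort()
                _, sign, a, b = cand[0]
                ep = p0[r] + sign * s[b] * n[r]
                en = p0[r] + sign * s[a] * n[r]
                val = s[b] - s[a]
            # allocate by the more distal (larger working-height) endpoint
            anchor = ep if ep[1] >= en[1] else en
            ox, oz = _to_original(anchor[0], anchor[1], swapped)
            origins.append((ox, j * sy, oz))
            values.append(val)

    values = np.asarray(values, dtype=float)
    origins = np.asarray(origins, dtype=float).reshape(-1, 3)
    keep = apply_thickness_cap(values, counts, max_thickness)
    values, origins = values[keep], origins[keep]
    if len(values) == 0:
        raise MethodFailureError(f"2D-CN produced zero samples for {structure}")
    sub, n_un = labeling.assign(origins, structure=structure)
    if n_un:
        counts["unassigned"] = n_un
    return ThicknessMap(
        method="2D-CN",
        structure=structure,
        origins=origins,
        values=values,
        subregions=sub,
        counts=counts,
    )


def thickness_surface_normals_2d(
    points: VoxelPointSet,
    labeling: SubregionLabeling,
    structure: str,
    *,
    domain_margin_frac: float = 0.1,
    max_thickness: float = MAX_PLAUSIBLE_THICKNESS_MM,
) -> ThicknessMap:
    counts: dict = {"slices_skipped": 0, "no_root": 0}
    sy = points.spacing[1]
    origins, values = [], []
    for j, swapped, ij in _slice_groups(points, labeling, structure):
        wsx, wsz = _working_spacing(points.spacing, swapped)
        cols, inv = np.unique(ij[:, 0], return_inverse=True)
        kmax = np.full(len(cols), -1)
        kmin = np.full(len(cols), np.iinfo(np.int64).max)
        np.maximum.at(kmax, inv, ij[:, 1])
        np.minimum.at(kmin, inv, ij[:, 1])
        xcol = cols * wsx
        try:
            fd = fit_slice_polynomial(xcol, kmax * wsz, "distal")
            fp = fit_slice_polynomial(xcol, kmin * wsz, "proximal")
        except SliceSkipped:
            counts["slices_skipped"] += 1
            continue
        margin = domain_margin_frac * (xcol.max() - xcol.min()) + 2.0 * wsx
        z0s = fd(xcol)
        ds = fd.deriv(xcol)
        for r, x0 in enumerate(xcol):
            z0 = z0s[r]
            d = ds[r]
            nrm = np.sqrt(1.0 + d * d)
            nx, nz = d / nrm, -1.0 / nrm  # unit normal toward proximal (smaller z)
            if abs(nx) < 1e-12:
                zi = fp(np.clip(x0, *fp.domain))
                sdist = z0 - zi
                if sdist <= 0:
                    counts["no_root"] += 1
                    continue
                val = float(sdist)
            else:
                m = nz / nx
                c = fp.coeffs.copy()
                c[2] -= m
                c[3] += m * x0 - z0
                roots = np.roots(c)
                real = roots[np.abs(roots.imag) < 1e-8 * np.maximum(1.0, np.abs(roots.real))].real
                real = real[(real >= fp.domain[0] - margin) & (real <= fp.domain[1] + margin)]
                svals = (real - x0) / nx
                sel = svals > 1e-9
                if not sel.any():
                    counts["no_root"] += 1
                    continue
                svals, real = svals[sel], real[sel]
                order = np.lexsort((np.abs(real - x0), svals))
                val = float(svals[order[0]])
            if val > max_thickness:
                counts["over_cap"] = counts.get("over_cap", 0) + 1
                continue
            ox, oz = _to_original(x0, z0, swapped)
            origins.append((ox, j * sy, oz))
            values.append(val)

    values = np.asarray(values, dtype=float)
    origins = np.asarray(origins, dtype=float).reshape(-1, 3)
    if len(values) == 0:
        raise MethodFailureError(f"2D-SN produced zero samples for {structure}")
    sub, n_un = labeling.assign(origins, structure=structure)
    if n_un:
        counts["unassigned"] = n_un
    return ThicknessMap(
        method="2D-SN",
        structure=structure,
        origins=origins,
        values=values,
        subregions=sub,
        counts=counts,
    )
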