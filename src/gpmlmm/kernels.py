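"""Kernels, their derivative blocks, and permutational symmetrization.

The vacuum (internal) kernel is a Matérn-5/2 on the Euclidean distance
between ID descriptors.  The environment kernel multiplies it by a
second-order polynomial (direct) kernel on the ESP descriptors,

    K_env = [(theta + V_i . V_j)^2 - theta^2] * K_internal .

Gaussian-process training on forces and charges needs mixed first
derivatives of the kernel with respect to the Cartesian coordinates of
either argument and with respect to the per-atom potentials.  All blocks
are assembled analytically via the chain rule through the descriptor
Jacobians.

Derivative convention (fixed here, used everywhere): subscript 1 refers
to the first kernel argument, subscript 2 to the second.  Prediction
code always places training configurations in argument 1 and the query
configuration in argument 2, exploiting kernel symmetry.

Permutational symmetry over chemically equivalent atoms replaces K by
(1/S^2) sum_{p,q} K(P_p r_i, P_q r_j); derivative rows/columns are mapped
back through the permutations.  Groups are supplied explicitly as index
lists (closure including the identity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .descriptors import esp_descriptor, inverse_distance_descriptor
from .geometry import Geometry, MMEnvironment

__all__ = [
    "KernelSpec",
    "KernelBlocks",
    "matern52",
    "direct_kernel",
    "internal_kernel_blocks",
    "env_kernel_blocks",
    "symmetrize",
    "Featurized",
    "featurize",
]


class KernelConfigError(ValueError):
    """Invalid kernel hyperparameters or permutation group."""


# ---------------------------------------------------------------------------
# scalar kernels
# ---------------------------------------------------------------------------

SQRT5 = np.sqrt(5.0)


def matern52(d, lengthscale: float):
    """Matérn kernel with nu = 5/2: (1 + c d + c^2 d^2 / 3) exp(-c d), c = sqrt(5)/λ."""
    if lengthscale <= 0:
        raise KernelConfigError(f"lengthscale must be > 0, got {lengthscale}")
    c = SQRT5 / lengthscale
    cd = c * np.asarray(d)
    return (1.0 + cd + cd * cd / 3.0) * np.exp(-cd)


def _matern52_phi(d, lengthscale: float):
    """k'(d)/d, smooth at d = 0:  -(c^2/3)(1 + c d) exp(-c d)."""
    c = SQRT5 / lengthscale
    cd = c * np.asarray(d)
    return -(c * c / 3.0) * (1.0 + cd) * np.exp(-cd)


def _matern52_psi(d, lengthscale: float):
    """(phi'(d))/d, smooth at d = 0:  (c^4/3) exp(-c d)."""
    c = SQRT5 / lengthscale
    cd = c * np.asarray(d)
    return (c ** 4 / 3.0) * np.exp(-cd)


def direct_kernel(v_i: np.ndarray, v_j: np.ndarray, theta: float = 1.0) -> float:
    """Second-order polynomial kernel on potential vectors: (θ + Vi·Vj)² − θ²."""
    v_i = np.asarray(v_i, dtype=float)
    v_j = np.asarray(v_j, dtype=float)
    if v_i.shape != v_j.shape:
        raise ValueError(f"potential length mismatch: {v_i.shape} vs {v_j.shape}")
    s = float(v_i @ v_j)
    return (theta + s) ** 2 - theta ** 2


# ---------------------------------------------------------------------------
# kernel specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KernelSpec:
    """Hyperparameters shared by both kernels.

    ``lengthscale`` is the Matérn λ in the units of the ID-descriptor
    distance (1/Angstrom).  ``theta`` is the polynomial intercept (the
    study default fixes θ = 1).  ``permutations`` is the full group of
    equivalent-atom permutations including the identity; the default is
    the identity-only group.
    """

    lengthscale: float
    theta: float = 1.0
    permutations: tuple[tuple[int, ...], ...] = ()

    def __post_init__(self) -> None:
        if self.lengthscale <= 0:
            raise KernelConfigError("lengthscale must be > 0")
        if self.theta < 0:
            raise KernelConfigError("theta must be >= 0")
        perms = tuple(tuple(int(i) for i in p) for p in self.permutations)
        object.__setattr__(self, "permutations", perms)

    def group(self, n_atoms: int) -> np.ndarray:
        """Permutation group as an (S, n_atoms) int array, identity first."""
        if not self.permutations:
            return np.arange(n_atoms)[None, :]
        perms = np.asarray(self.permutations, dtype=int)
        if perms.shape[1] != n_atoms:
            raise KernelConfigError(
                f"permutations act on {perms.shape[1]} atoms, geometry has {n_atoms}"
            )
        ident = np.arange(n_atoms)
        for p in perms:
            if not np.array_equal(np.sort(p), ident):
                raise KernelConfigError(f"not a permutation: {p.tolist()}")
        if not any(np.array_equal(p, ident) for p in perms):
            perms = np.vstack([ident[None, :], perms])
        return perms

    def validate_elements(self, symbols: tuple[str, ...]) -> None:
        for p in self.group(len(symbols)):
            for a, pa in enumerate(p):
                if symbols[a] != symbols[pa]:
                    raise KernelConfigError(
                        f"permutation maps atom {pa} ({symbols[pa]}) onto "
                        f"atom {a} ({symbols[a]}): unlike elements"
                    )


# ---------------------------------------------------------------------------
# featurization (descriptors of a configuration under one permutation)
# ---------------------------------------------------------------------------


@dataclass
class Featurized:
    """Descriptors of one configuration, Jacobians w.r.t. the *original*
    Cartesian coordinates, for one permutation of the atoms.

    ``atom_perm[a]`` is the original index of permuted atom ``a``; it maps
    potential-derivative components back to original atoms.
    """

    chi: np.ndarray  # (P,)
    jchi: np.ndarray | None  # (P, 3N)
    v: np.ndarray | None  # (N,)
    jv_qm: np.ndarray | None  # (N, 3N)
    jv_mm: np.ndarray | None  # (N, 3M)
    atom_perm: np.ndarray  # (N,)


def _scatter_cols(jac: np.ndarray, perm: np.ndarray) -> np.ndarray:
    """Map Jacobian columns of a permuted geometry back to original coords."""
    n = len(perm)
    out = np.empty_like(jac)
    cols = (3 * perm[:, None] + np.arange(3)[None, :]).reshape(-1)
    out[:, cols] = jac
    return out


def featurize(
    geom: Geometry,
    env: MMEnvironment | None,
    perm: np.ndarray,
    with_jacobians: bool = True,
    with_mm_jacobian: bool = False,
) -> Featurized:
    perm = np.asarray(perm, dtype=int)
    g = geom if np.array_equal(perm, np.arange(geom.n_atoms)) else geom.permuted(perm)
    idd = inverse_distance_descriptor(g, with_jacobian=with_jacobians)
    jchi = _scatter_cols(idd.jacobian, perm) if with_jacobians else None
    v = jv_qm = jv_mm = None
    if env is not None:
        esp = esp_descriptor(g, env, with_jacobians=with_jacobians or with_mm_jacobian)
        v = esp.values
        if with_jacobians:
            jv_qm = _scatter_cols(esp.jac_qm, perm)
        if with_mm_jacobian:
            jv_mm = esp.jac_mm
    return Featurized(idd.values, jchi, v, jv_qm, jv_mm, perm)


# ---------------------------------------------------------------------------
# vectorized pairwise blocks on stacked feature arrays
# ---------------------------------------------------------------------------


def internal_pair_blocks(
    chi1: np.ndarray,
    jchi1: np.ndarray | None,
    chi2: np.ndarray,
    jchi2: np.ndarray | None,
    lengthscale: float,
    *,
    grad1: bool = False,
    grad2: bool = False,
    hess: bool = False,
) -> dict[str, np.ndarray]:
    """Matérn-5/2 internal kernel blocks between stacked descriptor sets.

    ``chi1``: (m1, P), ``chi2``: (m2, P); Jacobians (m, P, G).  Returns a
    dict with ``k`` (m1, m2) and, on request, ``g1``/``g2`` (m1, m2, G)
    and ``h`` (m1, m2, G, G) — the mixed second derivative.
    """
    u = chi1[:, None, :] - chi2[None, :, :]  # (m1, m2, P)
    d = np.linalg.norm(u, axis=-1)
    out: dict[str, np.ndarray] = {"k": matern52(d, lengthscale)}
    phi = _matern52_phi(d, lengthscale)
    if grad1 or hess:
        w1 = np.einsum("xyp,xpg->xyg", u, jchi1)  # J1^T u
    if grad2 or hess:
        w2 = np.einsum("xyp,ypg->xyg", u, jchi2)  # J2^T u
    if grad1:
        out["g1"] = phi[..., None] * w1
    if grad2:
        out["g2"] = -phi[..., None] * w2
    if hess:
        psi = _matern52_psi(d, lengthscale)
        jj = np.einsum("xpg,yph->xygh", jchi1, jchi2)
        out["h"] = -phi[..., None, None] * jj - psi[..., None, None] * (
            w1[..., :, None] * w2[..., None, :]
        )
    return out


def env_pair_blocks(
    f1: dict[str, np.ndarray],
    f2: dict[str, np.ndarray],
    lengthscale: float,
    theta: float,
    *,
    grad1: bool = False,
    grad2: bool = False,
    hess: bool = False,
    dv1: bool = False,
    dv2: bool = False,
    g1_dv2: bool = False,
    dv1_dv2: bool = False,
    jv2_key: str = "jv",
) -> dict[str, np.ndarray]:
    """Environment-kernel blocks between stacked feature sets.

    ``f1``/``f2`` are dicts with keys ``chi`` (m, P), ``jchi`` (m, P, G),
    ``v`` (m, N) and ``jv`` (m, N, G).  ``jv2_key`` selects which Jacobian
    of the second argument the coordinate derivatives chain through (``jv``
    for QM coordinates, ``jv_mm`` for MM coordinates, where ``jchi`` of the
    second argument is then treated as zero).

    Returned keys (presence subject to flags):

    - ``k``        (m1, m2)            kernel value
    - ``g1``/``g2``(m1, m2, G)         d/d r_1, d/d r_2
    - ``h``        (m1, m2, G, G')     d^2/(d r_1 d r_2)
    - ``dv1``/``dv2`` (m1, m2, N)      d/d V_1a, d/d V_2a
    - ``sq1``/``sq2`` (m1, m2)         sum_a d/d V_a (charge rows)
    - ``g1_sq2``   (m1, m2, G)         d/d r_1 of sum_b d/d V_2b
    - ``sq1_g2``   (m1, m2, G')        sum_a d/d V_1a of d/d r_2
    - ``sq1_sq2``  (m1, m2)            sum_a sum_b mixed potential block
    - ``g1_dv2``   (m1, m2, G, N)      d/d r_1 of d/d V_2a
    - ``sq1_dv2``  (m1, m2, N)         sum_b d/d V_1b of d/d V_2a
    - ``dv1_dv2``  (m1, m2, N, N)      mixed per-atom potential block
    """
    chi1, jchi1, v1, jv1 = f1["chi"], f1.get("jchi"), f1["v"], f1.get("jv")
    chi2, v2 = f2["chi"], f2["v"]
    mm_side2 = jv2_key == "jv_mm"
    jchi2 = None if mm_side2 else f2.get("jchi")
    jv2 = f2.get(jv2_key)

    m = internal_pair_blocks(
        chi1, jchi1, chi2, jchi2, lengthscale,
        grad1=grad1 or hess or g1_dv2,
        grad2=(grad2 or hess) and not mm_side2,
        hess=hess and not mm_side2,
    )
    K_int = m["k"]
    s = np.einsum("xa,ya->xy", v1, v2)  # (m1, m2)
    ts = theta + s
    D = ts * ts - theta * theta
    sv1 = v1.sum(axis=1)  # (m1,)
    sv2 = v2.sum(axis=1)  # (m2,)

    out: dict[str, np.ndarray] = {"k": D * K_int}

    # ds/dr blocks (chain through the ESP Jacobians)
    if grad1 or hess or g1_dv2:
        ds1 = np.einsum("ya,xag->xyg", v2, jv1)  # (m1, m2, G)
    if grad2 or hess:
        ds2 = np.einsum("xa,yag->xyg", v1, jv2)  # (m1, m2, G')
    if grad1:
        g1 = D[..., None] * m["g1"] + (2.0 * ts * K_int)[..., None] * ds1
        out["g1"] = g1
    if grad2:
        gm2 = 0.0 if mm_side2 else m["g2"]
        out["g2"] = (
            (D[..., None] * gm2 if not mm_side2 else np.zeros_like(ds2))
            + (2.0 * ts * K_int)[..., None] * ds2
        )
    if hess:
        # H[g,h] = D hM + 2(θ+s)(gM1⊗ds2 + ds1⊗gM2) + 2M ds1⊗ds2 + 2(θ+s)M J1ᵀJ2
        h = 2.0 * K_int[..., None, None] * (ds1[..., :, None] * ds2[..., None, :])
        jj = np.einsum("xag,yah->xygh", jv1, jv2)
        h += (2.0 * ts * K_int)[..., None, None] * jj
        if not mm_side2:
            h += D[..., None, None] * m["h"]
            h += (2.0 * ts)[..., None, None] * (
                m["g1"][..., :, None] * ds2[..., None, :]
                + ds1[..., :, None] * m["g2"][..., None, :]
            )
        else:
            h += (2.0 * ts)[..., None, None] * (
                m["g1"][..., :, None] * ds2[..., None, :]
            )
        out["h"] = h
    if dv1:
        out["dv1"] = (2.0 * ts * K_int)[..., None] * v2[None, :, :]
    if dv2:
        out["dv2"] = (2.0 * ts * K_int)[..., None] * v1[:, None, :]
    out["sq1"] = 2.0 * ts * K_int * sv2[None, :]
    out["sq2"] = 2.0 * ts * K_int * sv1[:, None]
    if grad1:
        # d/dr1 of [2(θ+s) ΣV1 K_int]  — charge row of arg 2 against force row of arg 1
        out["g1_sq2"] = (
            (2.0 * ts * sv1[:, None])[..., None] * m["g1"]
            + (2.0 * K_int * sv1[:, None])[..., None] * ds1
            + (2.0 * ts * K_int)[..., None] * jv1.sum(axis=1)[:, None, :]
        )
    if grad2 and not mm_side2:
        out["sq1_g2"] = (
            (2.0 * ts * sv2[None, :])[..., None] * m["g2"]
            + (2.0 * K_int * sv2[None, :])[..., None] * ds2
            + (2.0 * ts * K_int)[..., None] * jv2.sum(axis=1)[None, :, :]
        )
    elif grad2 and mm_side2:
        out["sq1_g2"] = (
            (2.0 * K_int * sv2[None, :])[..., None] * ds2
            + (2.0 * ts * K_int)[..., None] * jv2.sum(axis=1)[None, :, :]
        )
    out["sq1_sq2"] = K_int * (
        2.0 * sv1[:, None] * sv2[None, :] + 2.0 * ts * v1.shape[1]
    )
    if g1_dv2:
        # d/dr1 of [2(θ+s) V1a K_int]  -> (m1, m2, G, N)
        t1 = (2.0 * ts)[..., None, None] * (
            m["g1"][..., :, None] * v1[:, None, None, :]
        )
        t2 = 2.0 * K_int[..., None, None] * (ds1[..., :, None] * v1[:, None, None, :])
        t3 = (2.0 * ts * K_int)[..., None, None] * np.transpose(jv1, (0, 2, 1))[:, None, :, :]
        out["g1_dv2"] = t1 + t2 + t3
    if dv2:
        # sum_b d/dV_1b of [2(θ+s) V_1a K_int] = K_int [2 ΣV2 V_1a + 2(θ+s)]
        out["sq1_dv2"] = K_int[..., None] * (
            2.0 * sv2[None, :, None] * v1[:, None, :] + (2.0 * ts)[..., None]
        )
    if dv1_dv2:
        out["dv1_dv2"] = K_int[..., None, None] * (
            2.0 * v2[None, :, :, None] * v1[:, None, None, :]
            + (2.0 * ts)[..., None, None] * np.eye(v1.shape[1])
        )
    out["k_int"] = K_int
    return out


# ---------------------------------------------------------------------------
# per-pair blocks (symmetrized), the API used by tests and small problems
# ---------------------------------------------------------------------------


@dataclass
class KernelBlocks:
    """All derivative blocks of one kernel evaluation K(arg1, arg2).

    Cartesian blocks are indexed by the *original* (unpermuted) coordinates
    of either argument; per-atom potential blocks by original atoms.
    ``grad_i_dV_j[g, a]`` is d2K/(dr_{1,g} dV_{2,a});
    ``dVi_dVj[a, b]`` is d2K/(dV_{1,a} dV_{2,b}).
    """

    k: float
    grad_i: np.ndarray | None = None
    grad_j: np.ndarray | None = None
    hess: np.ndarray | None = None
    dV_i: np.ndarray | None = None
    dV_j: np.ndarray | None = None
    grad_i_dV_j: np.ndarray | None = None
    dVi_dVj: np.ndarray | None = None
    mm_grad_j: np.ndarray | None = None


def _feature_dict(feats: list[Featurized]) -> dict[str, np.ndarray]:
    out = {"chi": np.stack([f.chi for f in feats])}
    if feats[0].jchi is not None:
        out["jchi"] = np.stack([f.jchi for f in feats])
    if feats[0].v is not None:
        out["v"] = np.stack([f.v for f in feats])
        if feats[0].jv_qm is not None:
            out["jv"] = np.stack([f.jv_qm for f in feats])
        if feats[0].jv_mm is not None:
            out["jv_mm"] = np.stack([f.jv_mm for f in feats])
    return out


def _perm_matrix(perms: np.ndarray) -> np.ndarray:
    """(S, N, N) scatter matrices: row a of permuted vector -> original atom perms[a]."""
    s, n = perms.shape
    mats = np.zeros((s, n, n))
    for i in range(s):
        mats[i, perms[i], np.arange(n)] = 1.0
    return mats


def internal_kernel_blocks(
    geom_i: Geometry, geom_j: Geometry, spec: KernelSpec
) -> KernelBlocks:
    """Symmetrized Matérn-5/2 internal-kernel blocks between two geometries."""
    if geom_i.n_atoms != geom_j.n_atoms:
        raise ValueError("geometries must have equal atom counts")
    spec.validate_elements(geom_i.symbols)
    group = spec.group(geom_i.n_atoms)
    fi = [featurize(geom_i, None, p) for p in group]
    fj = [featurize(geom_j, None, p) for p in group]
    di, dj = _feature_dict(fi), _feature_dict(fj)
    b = internal_pair_blocks(
        di["chi"], di["jchi"], dj["chi"], dj["jchi"], spec.lengthscale,
        grad1=True, grad2=True, hess=True,
    )
    s2 = len(group) ** 2
    return KernelBlocks(
        k=float(b["k"].sum() / s2),
        grad_i=b["g1"].sum(axis=(0, 1)) / s2,
        grad_j=b["g2"].sum(axis=(0, 1)) / s2,
        hess=b["h"].sum(axis=(0, 1)) / s2,
    )


def env_kernel_blocks(
    geom_i: Geometry,
    env_i: MMEnvironment,
    geom_j: Geometry,
    env_j: MMEnvironment,
    spec: KernelSpec,
) -> KernelBlocks:
    """Symmetrized environment-kernel blocks (direct x internal) between two
    solvated configurations, including potential-derivative and MM-coordinate
    blocks of the second argument."""
    if geom_i.n_atoms != geom_j.n_atoms:
        raise ValueError("geometries must have equal atom counts")
    spec.validate_elements(geom_i.symbols)
    group = spec.group(geom_i.n_atoms)
    fi = [featurize(geom_i, env_i, p) for p in group]
    fj = [featurize(geom_j, env_j, p, with_mm_jacobian=True) for p in group]
    di, dj = _feature_dict(fi), _feature_dict(fj)
    b = env_pair_blocks(
        di, dj, spec.lengthscale, spec.theta,
        grad1=True, grad2=True, hess=True, dv1=True, dv2=True,
        g1_dv2=True, dv1_dv2=True,
    )
    s = len(group)
    s2 = s * s
    pm = _perm_matrix(group)  # (S, N, N)
    # map potential-derivative components back to original atoms
    dv_i = np.einsum("xab,xyb->a", pm, b["dv1"]) / s2
    dv_j = np.einsum("yab,xyb->a", pm, b["dv2"]) / s2
    g1dv2 = np.einsum("yab,xygb->ga", pm, b["g1_dv2"]) / s2
    dvdv = np.einsum("xac,ybd,xycd->ab", pm, pm, b["dv1_dv2"]) / s2
    out = KernelBlocks(
        k=float(b["k"].sum() / s2),
        grad_i=b["g1"].sum(axis=(0, 1)) / s2,
        grad_j=b["g2"].sum(axis=(0, 1)) / s2,
        hess=b["h"].sum(axis=(0, 1)) / s2,
        dV_i=dv_i,
        dV_j=dv_j,
        grad_i_dV_j=g1dv2,
        dVi_dVj=dvdv,
    )
    if not env_j.is_empty:
        bm = env_pair_blocks(
            di, dj, spec.lengthscale, spec.theta, grad2=True, jv2_key="jv_mm",
        )
        out.mm_grad_j = bm["g2"].sum(axis=(0, 1)) / s2
    return out


def symmetrize(block_fn, permutations):
    """Wrap a two-geometry block function into its group average.

    ``block_fn(geom_i, geom_j, *args, **kwargs) -> KernelBlocks`` is
    evaluated on all pairs of permuted arguments; gradient/Hessian rows and
    columns and per-atom potential derivatives are mapped back through the
    permutations.  An identity-only group returns ``block_fn`` itself, so
    results are bit-for-bit identical to the unsymmetrized call.
    """
    perms = [np.asarray(p, dtype=int) for p in permutations]
    if not perms:
        return block_fn
    ident = np.arange(len(perms[0]))
    if not any(np.array_equal(p, ident) for p in perms):
        perms.append(ident)
    if len(perms) == 1:
        return block_fn

    def _coord_scatter(vec, perm):
        out = np.empty_like(vec)
        cols = (3 * perm[:, None] + np.arange(3)[None, :]).reshape(-1)
        out[cols] = vec
        return out

    def _atom_scatter(vec, perm):
        out = np.empty_like(vec)
        out[perm] = vec
        return out

    def wrapped(geom_i, geom_j, *args, **kwargs):
        acc = None
        for p in perms:
            for q in perms:
                b = block_fn(geom_i.permuted(p), geom_j.permuted(q), *args, **kwargs)
                mapped = KernelBlocks(k=b.k)
                if b.grad_i is not None:
                    mapped.grad_i = _coord_scatter(b.grad_i, p)
                if b.grad_j is not None:
                    mapped.grad_j = _coord_scatter(b.grad_j, q)
                if b.hess is not None:
                    h = np.empty_like(b.hess)
                    rows = (3 * p[:, None] + np.arange(3)[None, :]).reshape(-1)
                    cols = (3 * q[:, None] + np.arange(3)[None, :]).reshape(-1)
                    h[np.ix_(rows, cols)] = b.hess
                    mapped.hess = h
                if b.dV_i is not None:
                    mapped.dV_i = _atom_scatter(b.dV_i, p)
                if b.dV_j is not None:
                    mapped.dV_j = _atom_scatter(b.dV_j, q)
                if b.mm_grad_j is not None:
                    mapped.mm_grad_j = b.mm_grad_j
                if acc is None:
                    acc = mapped
                else:
                    for name in (
                        "grad_i", "grad_j", "hess", "dV_i", "dV_j", "mm_grad_j"
                    ):
                        v = getattr(mapped, name)
                        if v is not None:
                            setattr(acc, name, getattr(acc, name) + v)
                    acc.k += mapped.k
        s2 = len(perms) ** 2
        acc.k /= s2
        for name in ("grad_i", "grad_j", "hess", "dV_i", "dV_j", "mm_grad_j"):
            v = getattr(acc, name)
            if v is not None:
                setattr(acc, name, v / s2)
        return acc

    return wrapped
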