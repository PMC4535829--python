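"""Seeded generators and exact structural perturbations for C-alpha traces.

Everything here is geometry-only plumbing with known ground truth: ideal
helices, fixed-bond self-avoiding random walks, isometries, mirrors,
reversals, circular index shifts, bounded epsilon-perturbations and single
indels.  The walks use a 3.8 Angstrom step (the canonical trans C-alpha
spacing) with a 1.0 Angstrom clash floor between non-consecutive points;
they are not physical backbones (no dihedral statistics), just traces with
realistic scale.  All randomness flows through ``numpy.random.default_rng``
(PCG64), so a fixed seed is bit-reproducible across platforms.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from scipy.spatial.transform import Rotation

from .fragment import CAlphaFragment

__all__ = [
    "GeneratorConfig",
    "make_helix",
    "make_random_walk",
    "rotate",
    "translate",
    "mirror",
    "reverse",
    "circular_shift",
    "transform",
    "perturb_epsilon",
    "apply_indel",
    "make_family",
]

# fixture constants for the ideal alpha-helical trace
HELIX_RADIUS = 2.3  # Angstrom
HELIX_RISE = 1.5  # Angstrom per residue
HELIX_TWIST = 100.0  # degrees per residue

BOND_LENGTH = 3.8  # Angstrom, consecutive C-alpha spacing
CLASH_DISTANCE = 1.0  # Angstrom, minimum non-consecutive separation


@dataclass(frozen=True)
class GeneratorConfig:
    """A reproducible fragment recipe: same config, bit-identical fragment."""

    seed: int
    length: int
    bond_length: float = BOND_LENGTH
    kind: str = "random_walk"  # "helix" | "random_walk"

    def build(self) -> CAlphaFragment:
        if self.kind == "helix":
            return make_helix(self.length, self.seed)
        if self.kind == "random_walk":
            return make_random_walk(self.length, self.seed, bond_length=self.bond_length)
        raise ValueError(f"unknown generator kind {self.kind!r}")


def make_helix(length: int, seed: Optional[int] = None) -> CAlphaFragment:
    """Ideal alpha-helical C-alpha trace, optionally in a seeded random pose.

    Radius 2.3 A, rise 1.5 A/residue, twist 100 deg/residue.  With a seed the
    helix is rotated and translated by a random isometry (same seed, same
    pose); without one it sits on the canonical z-axis.
    """
    if length < 2:
        raise ValueError("length must be >= 2")
    t = np.arange(length) * np.deg2rad(HELIX_TWIST)
    coords = np.column_stack(
        [HELIX_RADIUS * np.cos(t), HELIX_RADIUS * np.sin(t), HELIX_RISE * np.arange(length)]
    )
    frag_id = f"helix-L{length}"
    if seed is not None:
        rng = np.random.default_rng(seed)
        rot = Rotation.random(rng=rng).as_matrix()
        shift = rng.uniform(-50.0, 50.0, size=3)
        coords = coords @ rot.T + shift
        frag_id = f"helix-L{length}-s{seed}"
    return CAlphaFragment(coords, id=frag_id)


def make_random_walk(
    length: int,
    seed: int,
    bond_length: float = BOND_LENGTH,
    clash_distance: float = CLASH_DISTANCE,
    max_tries: int = 1000,
) -> CAlphaFragment:
    """Fixed-bond random walk with uniformly random step directions.

    Steps that bring the new point within ``clash_distance`` of any earlier
    non-consecutive point are resampled (up to ``max_tries`` per step).
    """
    if length < 2:
        raise ValueError("length must be >= 2")
    rng = np.random.default_rng(seed)
    pts = np.zeros((length, 3))
    for i in range(1, length):
        for _ in range(max_tries):
            v = rng.normal(size=3)
            norm = np.linalg.norm(v)
            if norm == 0.0:
                continue
            cand = pts[i - 1] + bond_length * v / norm
            if i < 2:
                break
            gaps = np.linalg.norm(pts[: i - 1] - cand, axis=1)
            if np.all(gaps >= clash_distance):
                break
        else:
            raise RuntimeError(
                f"could not place residue {i} without a clash in {max_tries} tries"
            )
        pts[i] = cand
    return CAlphaFragment(pts, id=f"walk-L{length}-s{seed}")


def make_stiff_walk(
    length: int,
    seed: int,
    stiffness: float = 3.0,
    bond_length: float = BOND_LENGTH,
) -> CAlphaFragment:
    """Directionally persistent walk: an extended, strand-like trace.

    Each step direction is the previous one scaled by ``stiffness`` plus
    unit Gaussian noise, renormalized; stiffness 0 recovers an ordinary
    random walk, larger values give straighter (more extended) traces.
    """
    if length < 2:
        raise ValueError("length must be >= 2")
    rng = np.random.default_rng(seed)
    pts = np.zeros((length, 3))
    d = rng.normal(size=3)
    d /= np.linalg.norm(d)
    for i in range(1, length):
        d = stiffness * d + rng.normal(size=3)
        d /= np.linalg.norm(d)
        pts[i] = pts[i - 1] + bond_length * d
    return CAlphaFragment(pts, id=f"stiff-L{length}-s{seed}")


def rotate(fragment: CAlphaFragment, seed: Optional[int] = None,
           matrix: Optional[np.ndarray] = None) -> CAlphaFragment:
    """Apply a proper rotation: either a given matrix or a seeded random one."""
    if matrix is None:
        rng = np.random.default_rng(seed)
        matrix = Rotation.random(rng=rng).as_matrix()
    return fragment.with_coords(fragment.coords @ np.asarray(matrix).T)


def translate(fragment: CAlphaFragment, shift: Iterable[float]) -> CAlphaFragment:
    return fragment.with_coords(fragment.coords + np.asarray(list(shift), float))


def mirror(fragment: CAlphaFragment) -> CAlphaFragment:
    """Reflect through the yz-plane (negate x): the mirror-image trace."""
    coords = fragment.coords.copy()
    coords[:, 0] *= -1.0
    return fragment.with_coords(coords)


def reverse(fragment: CAlphaFragment) -> CAlphaFragment:
    """Sequential inversion: residues in reverse order, coordinates unchanged."""
    return fragment.with_coords(fragment.coords[::-1])


def circular_shift(fragment: CAlphaFragment, s: int) -> CAlphaFragment:
    """Circularly re-index residues by s, so that D_{P>>s} = roll(D_P, s).

    The returned trace visits the same points in the cyclically shifted
    order; its distance matrix is the input's rolled by s along both axes.
    """
    n = len(fragment)
    if not 0 <= s < n:
        raise ValueError(f"shift must satisfy 0 <= s < {n}, got {s}")
    return fragment.with_coords(np.roll(fragment.coords, s, axis=0))


_TRANSFORMS = {
    "rotate": rotate,
    "translate": translate,
    "mirror": mirror,
    "reverse": reverse,
    "circular_shift": circular_shift,
}


def transform(fragment: CAlphaFragment, op: str, **kwargs) -> CAlphaFragment:
    """Dispatch to one of rotate/translate/mirror/reverse/circular_shift."""
    try:
        fn = _TRANSFORMS[op]
    except KeyError:
        raise ValueError(f"unknown transform {op!r}; options: {sorted(_TRANSFORMS)}")
    return fn(fragment, **kwargs)


def perturb_epsilon(fragment: CAlphaFragment, epsilon: float, seed: int) -> CAlphaFragment:
    """Displace every point independently, uniformly within the epsilon-ball.

    Radii are drawn by cube-root inversion so the displacement is uniform in
    the ball; ``||x - f(x)|| <= epsilon`` holds for every point, the premise
    of the 2N*epsilon perturbation bound on the spectral distance.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if epsilon == 0.0:
        return fragment
    rng = np.random.default_rng(seed)
    n = len(fragment)
    dirs = rng.normal(size=(n, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    radii = epsilon * rng.uniform(size=n) ** (1.0 / 3.0)
    return fragment.with_coords(fragment.coords + radii[:, None] * dirs)


def apply_indel(
    fragment: CAlphaFragment, position: int, kind: str, seed: int = 0
) -> CAlphaFragment:
    """Delete the residue at ``position`` or insert one after it.

    An inserted point sits 3.8 A from both flanking residues (on the circle
    of geometrically feasible placements, seeded random choice); insertion
    after the last residue extends the chain by a random 3.8 A step.  All
    other coordinates are untouched.
    """
    n = len(fragment)
    if not 0 <= position < n:
        raise ValueError(f"position must be in [0, {n}), got {position}")
    coords = np.asarray(fragment.coords)
    if kind == "delete":
        if n - 1 < 2:
            raise ValueError("deletion would leave fewer than 2 residues")
        return fragment.with_coords(np.delete(coords, position, axis=0))
    if kind != "insert":
        raise ValueError(f"kind must be 'insert' or 'delete', got {kind!r}")
    rng = np.random.default_rng(seed)
    if position == n - 1:
        v = rng.normal(size=3)
        new_pt = coords[-1] + BOND_LENGTH * v / np.linalg.norm(v)
        return fragment.with_coords(np.vstack([coords, new_pt]))
    a, b = coords[position], coords[position + 1]
    gap = np.linalg.norm(b - a)
    if gap >= 2 * BOND_LENGTH:
        raise ValueError(
            f"neighbors are {gap:.2f} A apart; no point can be {BOND_LENGTH} A from both"
        )
    mid = (a + b) / 2
    h = np.sqrt(BOND_LENGTH**2 - (gap / 2) ** 2)
    axis = (b - a) / gap
    # random unit vector perpendicular to the neighbor axis
    u = rng.normal(size=3)
    u -= axis * (u @ axis)
    u /= np.linalg.norm(u)
    new_pt = mid + h * u
    return fragment.with_coords(
        np.vstack([coords[: position + 1], new_pt, coords[position + 1 :]])
    )


def make_family(
    seed: int,
    length: int = 23,
    n_perturbed: int = 6,
    n_indel: int = 3,
    n_decoys: int = 40,
    epsilon: float = 0.5,
    equal_length_only: bool = False,
) -> tuple[list[CAlphaFragment], dict[str, bool]]:
    """A desk-scale retrieval benchmark: one structural family among decoys.

    The family is a base random walk plus epsilon-perturbed copies (0.5 A
    displacement bound, a thermal-scale deformation) and, unless
    ``equal_length_only`` is set, single-indel variants — mimicking a motif
    family with insertion sites.  Decoys cycle through three structural
    classes (compact random walks, helices in random poses, extended stiff
    walks) so the control bank is class-diverse, the way a representative
    background fragment set is.  Returns the fragment list (base first) and
    a relevance map id -> is-family-member.
    """
    rng = np.random.default_rng(seed)
    base = make_random_walk(length, seed=int(rng.integers(2**31)))
    base = base.with_coords(base.coords, id=f"fam{seed}-base")
    frags: list[CAlphaFragment] = [base]
    labels: dict[str, bool] = {base.id: True}
    for i in range(n_perturbed):
        f = perturb_epsilon(base, epsilon, seed=int(rng.integers(2**31)))
        f = f.with_coords(f.coords, id=f"fam{seed}-pert{i}")
        frags.append(f)
        labels[f.id] = True
    if not equal_length_only:
        for i in range(n_indel):
            kind = "insert" if i % 2 == 0 else "delete"
            pos = int(rng.integers(1, length - 1))
            f = apply_indel(base, pos, kind, seed=int(rng.integers(2**31)))
            f = f.with_coords(f.coords, id=f"fam{seed}-{kind}{i}")
            frags.append(f)
            labels[f.id] = True
    makers = (make_random_walk, lambda L, s: make_helix(L, seed=s), make_stiff_walk)
    for i in range(n_decoys):
        f = makers[i % 3](length, int(rng.integers(2**31)))
        f = f.with_coords(f.coords, id=f"fam{seed}-decoy{i}")
        frags.append(f)
        labels[f.id] = False
    return frags, labels
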