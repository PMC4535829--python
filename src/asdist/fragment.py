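"""The C-alpha fragment container shared by every module.

A protein fragment is identified with the ordered sequence of its backbone
alpha-carbon coordinates ``p_1, ..., p_N`` in Angstrom.  All scores in this
package are functions of these traces only — no sequence, no side chains.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "CAlphaFragment",
    "FragmentSource",
    "InvalidFragmentError",
    "LengthMismatchError",
]


class InvalidFragmentError(ValueError):
    """Raised when coordinates violate the fragment invariants."""


class LengthMismatchError(ValueError):
    """Raised by scores that require equal-length fragments.

    The padded score :func:`asdist.spectral.asd` handles unequal lengths.
    """


@dataclass(frozen=True)
class FragmentSource:
    """Provenance of a fragment extracted from a structure file."""

    path: str
    chain: str
    first: int
    last: int


@dataclass(frozen=True)
class CAlphaFragment:
    """An ordered C-alpha trace.

    Parameters
    ----------
    coords
        ``(N, 3)`` array of coordinates in Angstrom, ``N >= 2``.
    id
        Free-text identifier used in rankings, matrices and manifests.
    source
        Optional provenance (file, chain, author residue range).
    """

    coords: np.ndarray
    id: str = ""
    source: Optional[FragmentSource] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=np.float64)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise InvalidFragmentError(
                f"coords must be an (N, 3) array, got shape {coords.shape}"
            )
        if coords.shape[0] < 2:
            raise InvalidFragmentError("a fragment needs at least 2 residues")
        if not np.all(np.isfinite(coords)):
            raise InvalidFragmentError("coordinates must be finite")
        steps = np.linalg.norm(np.diff(coords, axis=0), axis=1)
        if np.any(steps <= 0.0):
            raise InvalidFragmentError(
                "duplicated consecutive C-alpha positions (zero step length)"
            )
        coords = coords.copy()
        coords.setflags(write=False)
        object.__setattr__(self, "coords", coords)

    def __len__(self) -> int:
        return self.coords.shape[0]

    def with_coords(self, coords: np.ndarray, id: Optional[str] = None) -> "CAlphaFragment":
        """Return a copy with new coordinates (and optionally a new id)."""
        return CAlphaFragment(coords, self.id if id is None else id, self.source)


def as_fragment(obj, id: str = "") -> CAlphaFragment:
    """Coerce an ``(N, 3)`` array or fragment into a :class:`CAlphaFragment`."""
    if isinstance(obj, CAlphaFragment):
        return obj
    return CAlphaFragment(np.asarray(obj, dtype=np.float64), id=id)
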