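"""PDB C-alpha extraction, fragment windows, and TSV exchange formats.

Residue ranges are AUTHOR-NUMBERED and INCLUSIVE throughout: the spec string
``file.pdb:A:95-117`` selects 23 residues.  Only the first model of a
multi-model file is read.  Residues whose C-alpha has alternative locations
are rejected by default (``altloc="reject"``); ``altloc="occupancy"`` keeps
the highest-occupancy location instead.  HETATM C-alphas (e.g. MSE) are
accepted.  Insertion-coded residues inside the numeric range are kept in
file order.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Union

import gemmi
import numpy as np
import pandas as pd

from .fragment import CAlphaFragment, FragmentSource

__all__ = [
    "FragmentSpec",
    "GapError",
    "AltLocError",
    "parse_fragment_spec",
    "read_calpha",
    "write_calpha_pdb",
    "sliding_fragments",
    "read_distance_matrix_tsv",
    "write_distance_matrix_tsv",
    "read_manifest",
]


class GapError(ValueError):
    """A residue in the requested range has no C-alpha atom."""


class AltLocError(ValueError):
    """A residue has alternative C-alpha locations under the strict policy."""


@dataclass(frozen=True)
class FragmentSpec:
    """Addresses a fragment: file, chain, inclusive author residue range."""

    path: Union[str, Path]
    chain: str
    first: int
    last: int
    altloc: str = "reject"  # "reject" | "occupancy"

    def __post_init__(self) -> None:
        if self.first > self.last:
            raise ValueError(f"first ({self.first}) must be <= last ({self.last})")
        if self.altloc not in ("reject", "occupancy"):
            raise ValueError(f"altloc policy must be 'reject' or 'occupancy', got {self.altloc!r}")


def parse_fragment_spec(text: str, altloc: str = "reject") -> FragmentSpec:
    """Parse the project-wide ``path:chain:first-last`` addressing syntax."""
    try:
        path, chain, rng = text.rsplit(":", 2)
        first_s, last_s = rng.rsplit("-", 1)
        return FragmentSpec(path, chain, int(first_s), int(last_s), altloc)
    except (ValueError, IndexError) as exc:
        raise ValueError(
            f"cannot parse fragment spec {text!r}; expected path:chain:first-last"
        ) from exc


def read_calpha(spec: FragmentSpec) -> CAlphaFragment:
    """Read the ordered C-alpha trace for a fragment spec (first model only)."""
    structure = gemmi.read_structure(str(spec.path))
    if len(structure) == 0:
        raise ValueError(f"{spec.path}: no models")
    model = structure[0]
    chain = model.find_chain(spec.chain)
    if chain is None:
        raise ValueError(f"{spec.path}: no chain {spec.chain!r}")
    coords: list[list[float]] = []
    seen_nums: set[int] = set()
    for residue in chain:
        num = residue.seqid.num
        if not spec.first <= num <= spec.last:
            continue
        cas = [a for a in residue if a.name == "CA" and a.element != gemmi.Element("Ca")]
        if not cas:
            continue
        altlocs = {a.altloc for a in cas}
        if len(cas) > 1 or altlocs - {"\0", ""}:
            if spec.altloc == "reject":
                raise AltLocError(
                    f"{spec.path}:{spec.chain}:{num}{residue.seqid.icode.strip()} "
                    f"has alternative C-alpha locations {sorted(altlocs)}"
                )
            cas.sort(key=lambda a: (-a.occ, a.altloc))
        ca = cas[0]
        coords.append([ca.pos.x, ca.pos.y, ca.pos.z])
        seen_nums.add(num)
    missing = sorted(set(range(spec.first, spec.last + 1)) - seen_nums)
    if missing:
        raise GapError(
            f"{spec.path}:{spec.chain}: no C-alpha for residues {missing} "
            f"in range {spec.first}-{spec.last}"
        )
    frag_id = f"{Path(str(spec.path)).stem}:{spec.chain}:{spec.first}-{spec.last}"
    return CAlphaFragment(
        np.asarray(coords),
        id=frag_id,
        source=FragmentSource(str(spec.path), spec.chain, spec.first, spec.last),
    )


def write_calpha_pdb(fragment: CAlphaFragment, path: Union[str, Path],
                     chain: str = "A") -> None:
    """Write a minimal CA-only PDB file (GLY residues numbered from 1)."""
    lines = []
    for i, (x, y, z) in enumerate(fragment.coords, start=1):
        lines.append(
            f"ATOM  {i:5d}  CA  GLY {chain}{i:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}           C  "
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def sliding_fragments(structure: CAlphaFragment, window: int) -> List[CAlphaFragment]:
    """All L - window + 1 contiguous windows of a trace, offsets in the ids."""
    if window < 2:
        raise ValueError("window must be >= 2")
    length = len(structure)
    if window > length:
        warnings.warn(
            f"window {window} exceeds trace length {length}; no fragments",
            stacklevel=2,
        )
        return []
    out = []
    for offset in range(length - window + 1):
        frag = CAlphaFragment(
            structure.coords[offset : offset + window],
            id=f"{structure.id}[{offset}:{offset + window}]",
            source=structure.source,
        )
        out.append(frag)
    return out


def read_distance_matrix_tsv(path: Union[str, Path]) -> np.ndarray:
    """Square numeric TSV, no header, as written by other tools."""
    m = np.loadtxt(path, delimiter="\t", ndmin=2)
    if m.shape[0] != m.shape[1]:
        raise ValueError(f"{path}: matrix is {m.shape}, expected square")
    return m


def write_distance_matrix_tsv(matrix: np.ndarray, path: Union[str, Path]) -> None:
    np.savetxt(path, np.asarray(matrix), delimiter="\t", fmt="%.10g")


def read_manifest(path: Union[str, Path], altloc: str = "reject"
                  ) -> list[tuple[str, FragmentSpec, Optional[bool]]]:
    """Read a bank manifest TSV: columns id, path, chain, first, last[, label].

    ``label`` (when present) is ``positive`` or ``decoy``.  Relative fragment
    paths are resolved against the manifest's own directory.
    """
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "path": str, "chain": str})
    required = {"id", "path", "chain", "first", "last"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: manifest needs columns {sorted(required)}")
    base = Path(str(path)).parent
    rows = []
    for rec in df.itertuples(index=False):
        p = Path(rec.path)
        if not p.is_absolute():
            p = base / p
        spec = FragmentSpec(p, rec.chain, int(rec.first), int(rec.last), altloc)
        label: Optional[bool] = None
        if "label" in df.columns:
            label = str(rec.label).strip().lower() == "positive"
        rows.append((str(rec.id), spec, label))
    return rows
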