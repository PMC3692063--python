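"""Aligned protein families: residue encoding, match columns, identity matrices.

A family alignment is a fixed-width block of gapped amino-acid rows sharing a
single boolean match-column mask. The mask is chosen once per family so that
every subtree profile built from the family uses the same model coordinates,
which is what makes bit scores of different subtree models comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError

#: canonical 20-letter amino-acid alphabet (alphabetical one-letter codes)
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: unknown-residue symbol, encoded as index 20
UNKNOWN = "X"
ALPHABET = AMINO_ACIDS + UNKNOWN
GAP_CHARS = "-."

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_AA_INDEX[UNKNOWN] = 20

# Robinson & Robinson amino-acid background frequencies, order as AMINO_ACIDS.
BACKGROUND = np.array(
    [
        0.078047, 0.019246, 0.053640, 0.062949, 0.038556,
        0.073772, 0.021992, 0.051420, 0.057438, 0.090191,
        0.022425, 0.044873, 0.052028, 0.042644, 0.051295,
        0.071198, 0.058413, 0.064409, 0.013298, 0.032165,
    ]
)
BACKGROUND = BACKGROUND / BACKGROUND.sum()


def encode_residues(s: str) -> np.ndarray:
    """Encode a (possibly gapped) residue string: 0-19 amino acids, 20 = X, -1 = gap."""
    out = np.empty(len(s), dtype=np.int8)
    for i, c in enumerate(s.upper()):
        if c in GAP_CHARS:
            out[i] = -1
        else:
            try:
                out[i] = _AA_INDEX[c]
            except KeyError:
                raise ValueError(f"character {c!r} outside amino-acid alphabet")
    return out


@dataclass(eq=False)
class FamilyAlignment:
    """Equal-width gapped rows plus a shared boolean match-column mask."""

    row_ids: list[str]
    rows: list[str]
    match_mask: np.ndarray | None = None
    _encoded: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.row_ids) != len(self.rows):
            raise ValueError("row_ids and rows differ in length")
        if len(set(self.row_ids)) != len(self.row_ids):
            raise ValueError("duplicate row identifiers")
        if not self.rows:
            raise ValueError("empty alignment")
        width = len(self.rows[0])
        if any(len(r) != width for r in self.rows):
            raise ValueError("alignment rows have unequal lengths")
        if self.match_mask is not None:
            self.match_mask = np.asarray(self.match_mask, dtype=bool)
            if self.match_mask.shape != (width,):
                raise ValueError("match_mask length does not equal row length")
            if not self.match_mask.any():
                raise ValueError("match_mask has no match columns")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    @property
    def encoded(self) -> np.ndarray:
        """Integer matrix (n_rows, n_cols); gaps are -1, X is 20."""
        if self._encoded is None:
            self._encoded = np.vstack([encode_residues(r) for r in self.rows])
        return self._encoded

    def row_index(self, row_id: str) -> int:
        return self.row_ids.index(row_id)

    def ungapped(self, row_id: str) -> str:
        row = self.rows[self.row_index(row_id)]
        return "".join(c for c in row if c not in GAP_CHARS).upper()

    def subset(self, keep_ids: list[str]) -> "FamilyAlignment":
        """Alignment restricted to ``keep_ids`` (columns untouched, mask dropped)."""
        idx = [self.row_index(r) for r in keep_ids]
        return FamilyAlignment(list(keep_ids), [self.rows[i] for i in idx])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FamilyAlignment):
            return NotImplemented
        if self.row_ids != other.row_ids or self.rows != other.rows:
            return False
        if (self.match_mask is None) != (other.match_mask is None):
            return False
        if self.match_mask is None:
            return True
        return bool(np.array_equal(self.match_mask, other.match_mask))


def select_match_columns(alignment: FamilyAlignment, occupancy_min: float = 0.5) -> np.ndarray:
    """Mark columns whose non-gap occupancy is at least ``occupancy_min`` as match columns.

    The mask is computed once from the full family alignment and shared by all
    subtree profiles of the family.
    """
    enc = alignment.encoded
    occupancy = (enc >= 0).mean(axis=0)
    mask = occupancy >= occupancy_min
    if not mask.any():
        raise ConfigurationError(
            f"no column reaches occupancy {occupancy_min}; lower occupancy_min"
        )
    return mask


def pairwise_identity_matrix(alignment: FamilyAlignment) -> pd.DataFrame:
    """Fraction of identical residue pairs over columns where both rows have residues.

    The diagonal is 1.0 by definition; pairs with no co-occupied column get 0.0.
    """
    enc = alignment.encoded
    n = alignment.n_rows
    occ = enc >= 0
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            both = occ[i] & occ[j]
            denom = int(both.sum())
            if denom == 0:
                ident = 0.0
            else:
                ident = float((enc[i][both] == enc[j][both]).sum()) / denom
            out[i, j] = out[j, i] = ident
    return pd.DataFrame(out, index=alignment.row_ids, columns=alignment.row_ids)
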