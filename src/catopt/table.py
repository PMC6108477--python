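"""Probability tables over combination cells.

An estimated (or designed) joint distribution assigns a probability to every
combination cell of a :class:`~catopt.space.FactorSpace`.  Dense storage is
wasteful and often impossible (10^6+ cells), so a table is a mix of

* *uniform blocks* — a region plus the total mass spread uniformly over its
  cells (the natural output of a partition-tree posterior and of block
  structured truths), and
* *explicit cells* — a code matrix with one probability per row (the natural
  output of count-based and kernel estimators).

Cells covered by neither carry probability zero.
"""

from __future__ import annotations

import io
from typing import Sequence

import numpy as np
import pandas as pd

from .space import FactorSpace, Region

__all__ = ["ProbabilityTable"]

_DENSE_CELL_LIMIT = 20_000_000


class ProbabilityTable:
    """Sparse-capable map from combination cells to probabilities."""

    def __init__(
        self,
        space: FactorSpace,
        blocks: Sequence[tuple[Region, float]] | None = None,
        cell_codes: np.ndarray | None = None,
        cell_probs: np.ndarray | None = None,
    ) -> None:
        self.space = space
        self.blocks = [(r, float(m)) for r, m in (blocks or [])]
        for r, m in self.blocks:
            if m < 0:
                raise ValueError("block masses must be non-negative")
            if r.space is not space and r.space != space:
                raise ValueError("block region belongs to a different space")
        if cell_codes is None:
            cell_codes = np.empty((0, space.n_variables), dtype=np.int64)
            cell_probs = np.empty(0, dtype=np.float64)
        else:
            cell_codes = np.asarray(cell_codes, dtype=np.int64)
            cell_probs = np.asarray(cell_probs, dtype=np.float64)
            if cell_codes.shape != (cell_probs.size, space.n_variables):
                raise ValueError("cell_codes and cell_probs shapes disagree")
            if np.any(cell_probs < 0):
                raise ValueError("cell probabilities must be non-negative")
        self.cell_codes = cell_codes
        self.cell_probs = cell_probs

    # ------------------------------------------------------------------ mass
    def total(self) -> float:
        return float(
            sum(m for _, m in self.blocks) + self.cell_probs.sum()
        )

    def probability(self, cell: Sequence[str]) -> float:
        """Probability of one combination cell, given by category labels."""
        codes = np.asarray(self.space.encode_row(cell), dtype=np.int64)
        p = 0.0
        for region, mass in self.blocks:
            if region.contains(codes[None, :])[0]:
                p += mass / region.cell_count
        if self.cell_probs.size:
            match = np.all(self.cell_codes == codes, axis=1)
            p += float(self.cell_probs[match].sum())
        return p

    # ----------------------------------------------------------------- dense
    def to_dense(self, max_cells: int = _DENSE_CELL_LIMIT) -> np.ndarray:
        """Materialize the full cell array (shape = per-variable sizes)."""
        if self.space.n_cells > max_cells:
            raise ValueError(
                f"space has {self.space.n_cells} cells (> {max_cells}); "
                "refusing dense materialization"
            )
        arr = np.zeros(self.space.sizes, dtype=np.float64)
        for region, mass in self.blocks:
            arr[np.ix_(*region.subsets)] += mass / region.cell_count
        if self.cell_probs.size:
            np.add.at(arr, tuple(self.cell_codes.T), self.cell_probs)
        return arr

    @classmethod
    def from_dense(cls, space: FactorSpace, arr: np.ndarray) -> "ProbabilityTable":
        arr = np.asarray(arr, dtype=np.float64)
        if arr.shape != tuple(space.sizes):
            raise ValueError("dense array shape does not match the space")
        nz = np.nonzero(arr)
        codes = np.stack(nz, axis=1).astype(np.int64)
        return cls(space, cell_codes=codes, cell_probs=arr[nz])

    # -------------------------------------------------------------- sampling
    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw *n* i.i.d. cell codes (n x p) from the table."""
        comp_probs = np.concatenate(
            [[m for _, m in self.blocks], self.cell_probs]
        )
        if comp_probs.size == 0 or comp_probs.sum() <= 0:
            raise ValueError("cannot sample from an empty table")
        comp_probs = comp_probs / comp_probs.sum()
        picks = rng.choice(comp_probs.size, size=n, p=comp_probs)
        out = np.empty((n, self.space.n_variables), dtype=np.int64)
        n_blocks = len(self.blocks)
        for b, (region, _) in enumerate(self.blocks):
            idx = np.nonzero(picks == b)[0]
            for i, subset in enumerate(region.subsets):
                out[idx, i] = rng.choice(subset, size=idx.size)
        explicit = picks >= n_blocks
        if explicit.any():
            out[explicit] = self.cell_codes[picks[explicit] - n_blocks]
        return out

    # --------------------------------------------------------------- file IO
    def to_frame(self, max_cells: int = 2_000_000) -> pd.DataFrame:
        """Explicit (labels..., probability) frame of all nonzero cells."""
        arr = self.to_dense(max_cells=max_cells)
        nz = np.nonzero(arr)
        data = {
            name: [self.space.categories[i][j] for j in nz[i]]
            for i, name in enumerate(self.space.variable_names)
        }
        data["probability"] = arr[nz]
        return pd.DataFrame(data)

    def write_tsv(self, path, block_format: bool = False) -> None:
        """Write the table as TSV, prefixed by ``#var`` space-definition lines.

        Explicit format: one row per nonzero cell, label columns plus a
        ``probability`` column.  Block format: one row per uniform block,
        comma-joined label lists plus a ``mass`` column (requires a pure
        block table).
        """
        header = "".join(
            f"#var\t{name}\t{','.join(cats)}\n"
            for name, cats in zip(self.space.variable_names, self.space.categories)
        )
        if block_format:
            if self.cell_probs.size:
                raise ValueError("block format requires a pure block table")
            rows = {
                name: [
                    ",".join(r.subset_labels(i)) for r, _ in self.blocks
                ]
                for i, name in enumerate(self.space.variable_names)
            }
            rows["mass"] = [m for _, m in self.blocks]
            frame = pd.DataFrame(rows)
        else:
            frame = self.to_frame()
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(header)
            frame.to_csv(fh, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "ProbabilityTable":
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
        names, cats, body = [], [], []
        for line in text.splitlines():
            if line.startswith("#var\t"):
                _, name, labels = line.split("\t", 2)
                names.append(name)
                cats.append(labels.split(","))
            elif line.strip():
                body.append(line)
        if not names:
            raise ValueError("missing #var header lines")
        space = FactorSpace(names, cats)
        frame = pd.read_csv(io.StringIO("\n".join(body)), sep="\t", dtype=str)
        if "mass" in frame.columns:
            blocks = []
            for _, row in frame.iterrows():
                region = Region.from_labels(
                    space, [row[name].split(",") for name in names]
                )
                blocks.append((region, float(row["mass"])))
            return cls(space, blocks=blocks)
        codes = np.empty((frame.shape[0], len(names)), dtype=np.int64)
        for i, name in enumerate(names):
            codes[:, i] = [space.index_of(i, v) for v in frame[name]]
        probs = frame["probability"].astype(float).to_numpy()
        return cls(space, cell_codes=codes, cell_probs=probs)

    def __repr__(self) -> str:
        return (
            f"ProbabilityTable({len(self.blocks)} blocks, "
            f"{self.cell_probs.size} explicit cells, total={self.total():.6f})"
        )
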