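"""Readers and writers for expression matrices, linkage edges and network tables.

All files are tab-delimited UTF-8 text. Expression matrices are genes × samples
with a header row of sample IDs and gene IDs in the first column. Parsing is
strict: empty or "." cells in the numeric body are rejected so malformed
compendia fail fast instead of propagating NaNs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """A genes × samples real-valued expression matrix with unique IDs.

    Downstream code always indexes rows by gene ID, never by position, so the
    stored row/column order is purely cosmetic (it is preserved from the file).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = _duplicates(self.gene_ids)
            raise ValueError(f"duplicate gene IDs: {sorted(dupes)}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = _duplicates(self.sample_ids)
            raise ValueError(f"duplicate sample IDs: {sorted(dupes)}")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"value shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must all be finite")
        self._row_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, gene_id: str) -> np.ndarray:
        """Expression vector of one gene across samples."""
        try:
            return self.values[self._row_index[gene_id]]
        except KeyError:
            raise KeyError(f"gene {gene_id!r} not in matrix") from None

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._row_index

    def subset(self, gene_ids: list[str]) -> np.ndarray:
        """Rows for the given genes, stacked in the given order."""
        idx = [self._row_index[g] for g in gene_ids]
        return self.values[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class FunctionalLinkage:
    """Undirected functional-association edges (STRING-style) between genes.

    Used only to restrict each TF's candidate cofactors to its linkage
    neighbours; scores are carried along but never thresholded here.
    """

    edges: dict[frozenset, float | None] = field(default_factory=dict)

    def add(self, a: str, b: str, score: float | None = None) -> bool:
        if a == b:
            return False
        self.edges[frozenset((a, b))] = score
        return True

    def neighbors(self, gene: str) -> list[str]:
        out = set()
        for pair in self.edges:
            if gene in pair:
                other = (set(pair) - {gene}).pop()
                out.add(other)
        return sorted(out)

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class GeneRoleSets:
    """Role lists: TFs, candidate targets, and per-TF cofactor candidates."""

    tf_ids: list[str]
    candidate_target_ids: list[str] | None = None
    linkage: FunctionalLinkage | None = None

    def targets_for(self, expr: ExpressionMatrix) -> list[str]:
        """Candidate targets present in the matrix (all non-TF genes if unset)."""
        if self.candidate_target_ids is not None:
            return [g for g in self.candidate_target_ids if g in expr]
        tfset = set(self.tf_ids)
        return [g for g in expr.gene_ids if g not in tfset]

    def cofactors_for(self, tf: str, expr: ExpressionMatrix) -> list[str]:
        """Linkage neighbours of a TF that are present in the matrix."""
        if self.linkage is None:
            return []
        return [g for g in self.linkage.neighbors(tf) if g in expr and g != tf]


def _duplicates(ids) -> set:
    seen, dup = set(), set()
    for x in ids:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


def read_expression(path) -> ExpressionMatrix:
    """Read a genes × samples TSV (header = sample IDs, first column = gene IDs).

    Raises ``ValueError`` on duplicate gene IDs, ragged rows, or any cell that
    does not parse as a finite number (location reported).
    """
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        sample_ids = header[1:]
        if not sample_ids:
            raise ValueError(f"{path}: header has no sample IDs")
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(sample_ids) + 1:
                raise ValueError(
                    f"{path}:{lineno}: ragged row, expected "
                    f"{len(sample_ids) + 1} fields, got {len(parts)}"
                )
            gene = parts[0]
            vals = []
            for j, cell in enumerate(parts[1:], start=1):
                if cell in ("", "."):
                    raise ValueError(
                        f"{path}:{lineno}: empty/placeholder cell in column "
                        f"{j} (sample {sample_ids[j - 1]!r})"
                    )
                try:
                    vals.append(float(cell))
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: non-numeric cell {cell!r} in column "
                        f"{j} (sample {sample_ids[j - 1]!r})"
                    ) from None
            gene_ids.append(gene)
            rows.append(vals)
    dupes = _duplicates(gene_ids)
    if dupes:
        raise ValueError(f"{path}: duplicate gene ID(s): {sorted(dupes)}")
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return ExpressionMatrix(gene_ids, sample_ids, np.array(rows, dtype=float))


def write_expression(expr: ExpressionMatrix, path, float_format: str = "%.10g") -> None:
    expr.to_frame().to_csv(path, sep="\t", index_label="gene_id",
                           float_format=float_format)


def collapse_probes(probe_matrix: ExpressionMatrix, probe_map: dict) -> ExpressionMatrix:
    """Collapse a probe-level matrix to genes.

    ``probe_map`` maps each probe ID to a gene ID or a collection of gene IDs.
    Probes matching more than one gene are removed entirely; when several
    probes match a single gene the per-sample maximum over those probes is
    assigned to the gene. Probes absent from the map are dropped.
    """
    probe_genes: dict[str, list[str]] = {}
    for probe, genes in probe_map.items():
        if probe not in probe_matrix:
            raise KeyError(f"probe {probe!r} not present in matrix")
        glist = [genes] if isinstance(genes, str) else sorted(set(genes))
        probe_genes[probe] = glist

    gene_rows: dict[str, list[np.ndarray]] = {}
    n_multi = 0
    for probe, genes in probe_genes.items():
        if len(genes) != 1:
            n_multi += 1
            continue
        gene_rows.setdefault(genes[0], []).append(probe_matrix.row(probe))
    if n_multi:
        logger.info("collapse_probes: dropped %d multi-gene probes", n_multi)
    if not gene_rows:
        raise ValueError("no probes left after removing multi-gene probes")

    gene_ids = sorted(gene_rows)
    values = np.vstack([np.max(np.vstack(gene_rows[g]), axis=0) for g in gene_ids])
    return ExpressionMatrix(gene_ids, list(probe_matrix.sample_ids), values)


def read_linkage(path) -> FunctionalLinkage:
    """Read a 2- or 3-column TSV edge list into an undirected linkage set."""
    linkage = FunctionalLinkage()
    n_self = 0
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) not in (2, 3):
                raise ValueError(
                    f"{path}:{lineno}: expected 2 or 3 tab-separated fields, "
                    f"got {len(parts)}"
                )
            score = None
            if len(parts) == 3:
                try:
                    score = float(parts[2])
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: non-numeric score {parts[2]!r}"
                    ) from None
            if not linkage.add(parts[0], parts[1], score):
                n_self += 1
    if n_self:
        logger.info("read_linkage: dropped %d self-loop line(s)", n_self)
    return linkage


PAIR_COLUMNS = ["tf", "target", "mi", "p_value"]
TRIPLET_COLUMNS = ["modulator", "tf", "target", "mi_low", "mi_high", "cmi", "p_value"]


def write_network(pairs, triplets, pairs_path, triplets_path,
                  merged_path=None) -> None:
    """Write regulatory pairs and modulation triplets as TSV edge tables.

    Optionally also writes a single merged edge list with an ``edge_type``
    column (``regulation`` / ``modulation``) for graph-viewer import.
    """
    pair_df = pd.DataFrame(
        [(p.tf, p.target, p.mi, p.p_value) for p in pairs], columns=PAIR_COLUMNS
    )
    pair_df.to_csv(pairs_path, sep="\t", index=False, float_format="%.12g")

    trip_df = pd.DataFrame(
        [(t.modulator, t.tf, t.target, t.mi_low, t.mi_high, t.cmi, t.p_value)
         for t in triplets],
        columns=TRIPLET_COLUMNS,
    )
    trip_df.to_csv(triplets_path, sep="\t", index=False, float_format="%.12g")

    if merged_path is not None:
        rows = [(p.tf, p.target, "regulation") for p in pairs]
        rows += [(t.modulator, t.tf, "modulation") for t in triplets]
        pd.DataFrame(rows, columns=["source", "target", "edge_type"]).drop_duplicates(
        ).to_csv(merged_path, sep="\t", index=False)


def read_pairs(path):
    """Read back a Step-1 pairs table written by :func:`write_network`."""
    from .mi_inference import RegulatoryPair

    df = pd.read_csv(path, sep="\t")
    return [RegulatoryPair(r.tf, r.target, float(r.mi), float(r.p_value))
            for r in df.itertuples(index=False)]


def read_triplets(path):
    """Read back a Step-2 triplets table written by :func:`write_network`."""
    from .modulation import ModulationTriplet

    df = pd.read_csv(path, sep="\t")
    return [
        ModulationTriplet(r.modulator, r.tf, r.target, float(r.mi_low),
                          float(r.mi_high), float(r.p_value))
        for r in df.itertuples(index=False)
    ]
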