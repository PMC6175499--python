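"""Containers and I/O for longitudinal gene-expression data.

The central container is :class:`ExpressionDataset`: a genes x samples matrix
of log2 expression values where every sample is identified by an
``(individual_id, time)`` pair.  Data arrive either in a simple TSV dialect
(header ``gene<TAB>D1:0<TAB>D1:2.5 ...``, one row per gene) or as probe-level
microarray tables (a local GEO series-matrix file plus its platform
annotation), which are collapsed to gene level by taking the median over all
probes that map to the same gene symbol.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger("phaseloop")

Sample = tuple[str, float]

_TIME_UNITS = ("hours", "days")


def _parse_sample_header(header: str, column: int) -> Sample:
    """Split an ``individualID:time`` column header into its parts."""
    if ":" not in header:
        raise ValueError(
            f"sample column {column} header {header!r} is not of the form "
            "'individual:time'"
        )
    individual, _, time_str = header.rpartition(":")
    try:
        time = float(time_str)
    except ValueError:
        raise ValueError(
            f"sample column {column} header {header!r} has non-numeric time "
            f"{time_str!r}"
        ) from None
    return individual, time


@dataclass
class ExpressionDataset:
    """Genes x samples matrix of log2 expression with sample metadata.

    Parameters
    ----------
    genes
        Ordered gene symbols; duplicates are rejected.
    samples
        Ordered ``(individual_id, time)`` pairs, one per column; each pair
        must be unique and times must be nonnegative.
    values
        2-D array of log2 expression, shape ``(len(genes), len(samples))``.
    time_unit
        ``"hours"`` or ``"days"``.
    """

    genes: list[str]
    samples: list[Sample]
    values: np.ndarray
    time_unit: str = "hours"

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        self.samples = [(str(i), float(t)) for i, t in self.samples]
        self.values = np.asarray(self.values, dtype=float)
        seen: set[str] = set()
        for g in self.genes:
            if g in seen:
                raise ValueError(f"duplicate gene symbol {g!r}")
            seen.add(g)
        seen_samples: set[Sample] = set()
        for s in self.samples:
            if s in seen_samples:
                raise ValueError(
                    f"duplicate sample (individual={s[0]!r}, time={s[1]!r})"
                )
            seen_samples.add(s)
        if self.values.ndim != 2 or self.values.shape != (
            len(self.genes),
            len(self.samples),
        ):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        for ind, t in self.samples:
            if t < 0:
                raise ValueError(f"negative time {t} for individual {ind!r}")
        if self.time_unit not in _TIME_UNITS:
            raise ValueError(f"time_unit must be one of {_TIME_UNITS}")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def times(self) -> np.ndarray:
        """Sorted unique sampling times."""
        return np.unique([t for _, t in self.samples])

    @property
    def individuals(self) -> list[str]:
        """Individual ids in order of first appearance."""
        out: list[str] = []
        for ind, _ in self.samples:
            if ind not in out:
                out.append(ind)
        return out

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not present in dataset") from None

    def gene_values(self, gene: str) -> np.ndarray:
        return self.values[self.gene_index(gene)]

    def sample_index(self, individual: str, time: float) -> int:
        try:
            return self.samples.index((individual, float(time)))
        except ValueError:
            raise KeyError(
                f"no sample for individual {individual!r} at time {time}"
            ) from None

    def subset_individuals(self, individuals: Iterable[str]) -> "ExpressionDataset":
        keep = set(individuals)
        idx = [i for i, (ind, _) in enumerate(self.samples) if ind in keep]
        return ExpressionDataset(
            genes=list(self.genes),
            samples=[self.samples[i] for i in idx],
            values=self.values[:, idx].copy(),
            time_unit=self.time_unit,
        )

    def subset_samples(self, indices: Sequence[int]) -> "ExpressionDataset":
        return ExpressionDataset(
            genes=list(self.genes),
            samples=[self.samples[i] for i in indices],
            values=self.values[:, list(indices)].copy(),
            time_unit=self.time_unit,
        )

    def copy(self) -> "ExpressionDataset":
        return ExpressionDataset(
            genes=list(self.genes),
            samples=list(self.samples),
            values=self.values.copy(),
            time_unit=self.time_unit,
        )


@dataclass
class ProbeMatrix:
    """Probe-level expression matrix plus a probe -> gene symbol mapping.

    The mapping may be many-to-one (several probes per gene) and need not
    cover every probe; unmapped probes are dropped when collapsing.
    """

    probe_ids: list[str]
    samples: list[Sample]
    values: np.ndarray
    probe_to_gene: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.probe_ids = list(self.probe_ids)
        self.samples = [(str(i), float(t)) for i, t in self.samples]
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValueError("duplicate probe ids")
        unknown = set(self.probe_to_gene) - set(self.probe_ids)
        if unknown:
            raise ValueError(
                f"probe_to_gene maps probes absent from the matrix: {sorted(unknown)}"
            )
        if self.values.shape != (len(self.probe_ids), len(self.samples)):
            raise ValueError("values shape does not match probes x samples")


def read_expression_table(path, time_unit: str = "hours") -> ExpressionDataset:
    """Read the TSV dialect: header ``gene<TAB>ind:time...``, log2 values.

    Lines starting with ``#`` before the header are treated as comments
    (the simulator writes a ``# seed:`` provenance line).
    """
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header: list[str] | None = None
        genes: list[str] = []
        rows: list[list[float]] = []
        for line_no, row in enumerate(reader, start=1):
            if not row or (header is None and row[0].startswith("#")):
                continue
            if header is None:
                header = row
                continue
            genes.append(row[0])
            if len(row) != len(header):
                raise ValueError(
                    f"row {line_no} ({row[0]!r}) has {len(row) - 1} values, "
                    f"expected {len(header) - 1}"
                )
            vals = []
            for col, cell in enumerate(row[1:], start=1):
                try:
                    vals.append(float(cell))
                except ValueError:
                    raise ValueError(
                        f"non-numeric value {cell!r} at gene {row[0]!r} "
                        f"(row {line_no}), column {header[col]!r}"
                    ) from None
            rows.append(vals)
    if header is None:
        raise ValueError(f"empty expression file: {path}")
    samples = [
        _parse_sample_header(h, col) for col, h in enumerate(header[1:], start=1)
    ]
    values = np.array(rows, dtype=float) if rows else np.empty((0, len(samples)))
    return ExpressionDataset(
        genes=genes, samples=samples, values=values, time_unit=time_unit
    )


def write_expression_table(ds: ExpressionDataset, path, comments: Sequence[str] = ()) -> None:
    """Write a dataset in the TSV dialect (values to 6 decimal places)."""
    with open(path, "w", newline="") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        headers = [f"{ind}:{t:g}" for ind, t in ds.samples]
        fh.write("\t".join(["gene", *headers]) + "\n")
        for g, row in zip(ds.genes, ds.values):
            fh.write("\t".join([g, *(f"{v:.6f}" for v in row)]) + "\n")


def collapse_probes(pm: ProbeMatrix) -> ExpressionDataset:
    """Collapse a probe-level matrix to gene level by per-gene median.

    Probes without a gene mapping are dropped (counted in the log).  Gene
    order follows the first occurrence of each symbol among the probes, so
    collapsing an already gene-level matrix is the identity.
    """
    if not pm.probe_to_gene:
        raise ValueError("no mapped probes")
    gene_rows: dict[str, list[int]] = {}
    for i, probe in enumerate(pm.probe_ids):
        gene = pm.probe_to_gene.get(probe)
        if gene is None:
            continue
        gene_rows.setdefault(gene, []).append(i)
    n_unmapped = len(pm.probe_ids) - sum(len(v) for v in gene_rows.values())
    if n_unmapped:
        logger.info(
            "collapse_probes: dropped %d unmapped probe(s) of %d",
            n_unmapped,
            len(pm.probe_ids),
        )
    genes = list(gene_rows)
    values = np.vstack(
        [np.median(pm.values[rows, :], axis=0) for rows in gene_rows.values()]
    )
    return ExpressionDataset(genes=genes, samples=list(pm.samples), values=values)


def read_geo_series_matrix(
    matrix_path,
    annotation_path,
    *,
    probe_column: str,
    symbol_column: str,
    sample_metadata: Mapping[str, Sample],
) -> ProbeMatrix:
    """Parse a local GEO series-matrix file plus its GPL annotation table.

    The series-matrix preamble lines (starting ``!``) are skipped; the data
    table between ``!series_matrix_table_begin`` and ``_end`` supplies the
    probe matrix.  ``sample_metadata`` maps each GSM accession appearing in
    the table header to its ``(individual_id, time)`` pair, because GEO does
    not encode those uniformly.  No network access is performed.
    """
    probe_ids: list[str] = []
    rows: list[list[float]] = []
    accessions: list[str] | None = None
    in_table = False
    with open(matrix_path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if line.startswith("!series_matrix_table_end"):
                break
            if not in_table or not line:
                continue
            parts = [p.strip().strip('"') for p in line.split("\t")]
            if accessions is None:
                accessions = parts[1:]
                continue
            probe_ids.append(parts[0])
            rows.append([float(p) for p in parts[1:]])
    if accessions is None:
        raise ValueError(f"no series-matrix table found in {matrix_path}")
    missing = [a for a in accessions if a not in sample_metadata]
    if missing:
        raise ValueError(f"no sample metadata for accession(s): {missing}")
    samples = [sample_metadata[a] for a in accessions]

    probe_to_gene: dict[str, str] = {}
    with open(annotation_path) as fh:
        reader = csv.reader(
            (l for l in fh if not l.startswith(("#", "!", "^"))), delimiter="\t"
        )
        header = next(reader, None)
        if header is None:
            raise ValueError(f"empty annotation table: {annotation_path}")
        try:
            p_col = header.index(probe_column)
            s_col = header.index(symbol_column)
        except ValueError as exc:
            raise ValueError(
                f"annotation table lacks column: {exc}"
            ) from None
        for row in reader:
            if len(row) <= max(p_col, s_col):
                continue
            probe, symbol = row[p_col].strip(), row[s_col].strip()
            if probe and symbol:
                probe_to_gene[probe] = symbol
    probe_to_gene = {p: g for p, g in probe_to_gene.items() if p in set(probe_ids)}
    return ProbeMatrix(
        probe_ids=probe_ids,
        samples=list(samples),
        values=np.array(rows, dtype=float),
        probe_to_gene=probe_to_gene,
    )
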