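"""Domain types and readers for droplet count matrices, antibody panels, and staining conditions.

A droplet experiment couples per-barcode UMI count matrices from up to three
modalities (ADT = antibody-derived tags, HTO = hashtag oligos, RNA) with an
antibody panel sheet (staining concentration per condition in ug/mL) and a
record of the staining condition (dilution factor, volume, cell number,
tissue). All matrices are stored features x barcodes with nonnegative integer
counts; barcode strings are the public key across modalities.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

logger = logging.getLogger(__name__)

#: vendor conjugate suffixes stripped before matching ADT features to panel rows
DEFAULT_CONJUGATE_SUFFIXES = ("-TotalSeqC", "-TotalSeqB", "-TotalSeqA", "_TotalSeqC")

DROPLET_CLASSES = ("unassigned", "cell", "empty", "removed")


class FormatError(ValueError):
    """Raised when an input file violates the expected on-disk format."""


def strip_conjugate_suffix(name: str, suffixes: Sequence[str] = DEFAULT_CONJUGATE_SUFFIXES) -> str:
    for suffix in suffixes:
        if name.endswith(suffix):
            return name[: -len(suffix)]
    return name


@dataclass
class CountMatrix:
    """Nonnegative integer UMI counts, features x barcodes.

    ``counts`` is kept as a CSR sparse matrix; ``feature_ids`` and
    ``barcode_ids`` must be unique and consistent with its shape.
    """

    feature_ids: list[str]
    barcode_ids: list[str]
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.barcode_ids = [str(b) for b in self.barcode_ids]
        mat = self.counts
        if not sp.issparse(mat):
            mat = sp.csr_matrix(np.asarray(mat))
        mat = mat.tocsr()
        if np.issubdtype(mat.dtype, np.floating):
            if mat.nnz and not np.all(np.equal(np.mod(mat.data, 1), 0)):
                raise FormatError("count matrix contains non-integer entries")
            mat = mat.astype(np.int64)
        elif not np.issubdtype(mat.dtype, np.integer):
            raise FormatError(f"count matrix has non-numeric dtype {mat.dtype}")
        else:
            mat = mat.astype(np.int64)
        if mat.nnz and mat.data.min() < 0:
            raise FormatError("count matrix contains negative entries")
        if mat.shape != (len(self.feature_ids), len(self.barcode_ids)):
            raise ValueError(
                f"count matrix shape {mat.shape} inconsistent with "
                f"{len(self.feature_ids)} features x {len(self.barcode_ids)} barcodes"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicated feature ids")
        if len(set(self.barcode_ids)) != len(self.barcode_ids):
            raise ValueError("duplicated barcode ids")
        mat.eliminate_zeros()
        self.counts = mat

    # -- accessors -------------------------------------------------------

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_barcodes(self) -> int:
        return len(self.barcode_ids)

    def barcode_totals(self) -> pd.Series:
        totals = np.asarray(self.counts.sum(axis=0)).ravel()
        return pd.Series(totals, index=self.barcode_ids, name="total")

    def feature_totals(self) -> pd.Series:
        totals = np.asarray(self.counts.sum(axis=1)).ravel()
        return pd.Series(totals, index=self.feature_ids, name="total")

    def feature_vector(self, feature: str) -> np.ndarray:
        """Dense per-barcode counts for one feature."""
        try:
            idx = self.feature_ids.index(feature)
        except ValueError:
            raise KeyError(f"unknown feature {feature!r}") from None
        return np.asarray(self.counts[idx, :].todense()).ravel()

    def subset_barcodes(self, barcodes: Sequence[str]) -> "CountMatrix":
        index = {b: i for i, b in enumerate(self.barcode_ids)}
        cols = [index[b] for b in barcodes]
        return CountMatrix(list(self.feature_ids), list(barcodes), self.counts[:, cols])

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.to_dense(), index=self.feature_ids, columns=self.barcode_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CountMatrix":
        return cls(list(map(str, frame.index)), list(map(str, frame.columns)), sp.csr_matrix(frame.to_numpy()))


@dataclass
class StainingCondition:
    """One staining condition of the titration design.

    ``dilution_factor`` is relative to the starting panel (1 = starting
    concentration, 4 = fourfold diluted); ``volume_ul`` is the total staining
    volume and ``cells_stained`` the number of cells present during staining.
    """

    condition_id: str
    volume_ul: float
    cells_stained: float
    dilution_factor: float = 1.0
    tissue: str = "PBMC"

    def __post_init__(self) -> None:
        if self.dilution_factor <= 0:
            raise ValueError("dilution_factor must be > 0")
        if self.volume_ul <= 0:
            raise ValueError("volume_ul must be > 0")
        if self.cells_stained <= 0:
            raise ValueError("cells_stained must be > 0")


@dataclass
class AntibodyPanel:
    """Panel sheet: one row per marker, staining concentration per condition.

    Backed by a DataFrame indexed by marker name with columns
    ``concentration_<condition_id>`` (ug/mL), ``is_isotype_control`` and
    optionally ``expected_expressing_cluster``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        table = self.table.copy()
        table.index = table.index.map(str)
        if table.index.duplicated().any():
            dupes = sorted(table.index[table.index.duplicated()].unique())
            raise ValueError(f"duplicated marker names in panel: {dupes}")
        if "is_isotype_control" not in table.columns:
            table["is_isotype_control"] = False
        table["is_isotype_control"] = table["is_isotype_control"].astype(bool)
        conc_cols = [c for c in table.columns if c.startswith("concentration_")]
        if not conc_cols:
            raise ValueError("panel has no concentration_<condition_id> column")
        for col in conc_cols:
            table[col] = pd.to_numeric(table[col])
            if (table[col] < 0).any():
                raise ValueError(f"negative concentration in column {col}")
        self.table = table

    @property
    def markers(self) -> list[str]:
        return list(self.table.index)

    @property
    def condition_ids(self) -> list[str]:
        return [c[len("concentration_"):] for c in self.table.columns if c.startswith("concentration_")]

    def concentration(self, marker: str, condition_id: str) -> float:
        col = f"concentration_{condition_id}"
        if col not in self.table.columns:
            raise KeyError(f"panel has no concentrations for condition {condition_id!r}")
        if marker not in self.table.index:
            raise KeyError(f"unknown marker {marker!r}")
        return float(self.table.at[marker, col])

    def concentrations(self, condition_id: str) -> pd.Series:
        col = f"concentration_{condition_id}"
        if col not in self.table.columns:
            raise KeyError(f"panel has no concentrations for condition {condition_id!r}")
        return self.table[col].astype(float).rename(condition_id)

    def expected_cluster(self, marker: str) -> str | None:
        if "expected_expressing_cluster" not in self.table.columns:
            return None
        value = self.table.at[marker, "expected_expressing_cluster"]
        if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
            return None
        return str(value)

    def missing_features(
        self, feature_ids: Iterable[str], suffixes: Sequence[str] = DEFAULT_CONJUGATE_SUFFIXES
    ) -> list[str]:
        """ADT features with no panel row after conjugate-suffix stripping."""
        known = set(self.table.index)
        return [f for f in feature_ids if strip_conjugate_suffix(f, suffixes) not in known]

    @classmethod
    def read_csv(cls, path: str | Path) -> "AntibodyPanel":
        frame = pd.read_csv(path)
        if "name" not in frame.columns:
            raise FormatError(f"panel sheet {path} lacks a 'name' column")
        return cls(frame.set_index("name"))

    def write_csv(self, path: str | Path) -> None:
        self.table.rename_axis("name").reset_index().to_csv(path, index=False)


@dataclass
class DropletExperiment:
    """Aligned ADT/HTO/RNA matrices plus per-barcode metadata for one condition.

    ``metadata`` is indexed by barcode and carries ``droplet_class``
    (unassigned | cell | empty | removed), ``sample``, ``cell_type`` and any
    embedding coordinates supplied as inputs.
    """

    adt: CountMatrix
    panel: AntibodyPanel
    condition: StainingCondition
    hto: CountMatrix | None = None
    rna: CountMatrix | None = None
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        barcodes = self.adt.barcode_ids
        for name, modality in (("hto", self.hto), ("rna", self.rna)):
            if modality is not None and modality.barcode_ids != barcodes:
                raise ValueError(f"{name} barcodes differ from ADT barcodes; use build_experiment")
        if self.metadata.empty:
            self.metadata = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
        else:
            self.metadata = self.metadata.reindex(barcodes)
            self.metadata.index.name = "barcode"
        if "droplet_class" not in self.metadata.columns:
            self.metadata["droplet_class"] = "unassigned"
        bad = set(self.metadata["droplet_class"].unique()) - set(DROPLET_CLASSES)
        if bad:
            raise ValueError(f"invalid droplet classes {sorted(bad)}")

    @property
    def barcodes(self) -> list[str]:
        return self.adt.barcode_ids

    def barcodes_in_class(self, droplet_class: str) -> list[str]:
        mask = self.metadata["droplet_class"] == droplet_class
        return list(self.metadata.index[mask])

    @property
    def cell_barcodes(self) -> list[str]:
        return self.barcodes_in_class("cell")

    @property
    def empty_barcodes(self) -> list[str]:
        return self.barcodes_in_class("empty")

    def adt_by_class(self, droplet_class: str) -> CountMatrix:
        return self.adt.subset_barcodes(self.barcodes_in_class(droplet_class))


def build_experiment(
    adt: CountMatrix,
    panel: AntibodyPanel,
    condition: StainingCondition,
    rna: CountMatrix | None = None,
    hto: CountMatrix | None = None,
    metadata: pd.DataFrame | None = None,
    suffixes: Sequence[str] = DEFAULT_CONJUGATE_SUFFIXES,
) -> DropletExperiment:
    """Validate and align modalities into a DropletExperiment.

    Modalities are restricted to the intersection of their barcode sets (in
    ADT order); the number of dropped barcodes is logged. Every ADT feature
    must map to a panel row after conjugate-suffix stripping.
    """
    missing = panel.missing_features(adt.feature_ids, suffixes)
    if missing:
        raise ValueError(f"ADT features absent from panel: {missing}")
    shared = set(adt.barcode_ids)
    for modality in (rna, hto):
        if modality is not None:
            shared &= set(modality.barcode_ids)
    if not shared:
        raise ValueError("modalities share no barcodes")
    kept = [b for b in adt.barcode_ids if b in shared]
    n_dropped = (
        (adt.n_barcodes - len(kept))
        + sum(m.n_barcodes - len(kept) for m in (rna, hto) if m is not None)
    )
    if n_dropped:
        logger.info("build_experiment: dropped %d barcodes outside the modality intersection", n_dropped)
    adt = adt.subset_barcodes(kept) if len(kept) != adt.n_barcodes else adt
    if rna is not None and rna.barcode_ids != kept:
        rna = rna.subset_barcodes(kept)
    if hto is not None and hto.barcode_ids != kept:
        hto = hto.subset_barcodes(kept)
    meta = pd.DataFrame(index=pd.Index(kept, name="barcode"))
    if metadata is not None:
        meta = metadata.reindex(kept)
        meta.index.name = "barcode"
    if "droplet_class" not in meta.columns:
        meta["droplet_class"] = "unassigned"
    else:
        meta["droplet_class"] = meta["droplet_class"].fillna("unassigned")
    return DropletExperiment(adt=adt, panel=panel, condition=condition, hto=hto, rna=rna, metadata=meta)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _find_file(directory: Path, names: Sequence[str]) -> Path:
    for name in names:
        candidate = directory / name
        if candidate.exists():
            return candidate
    raise FileNotFoundError(f"none of {list(names)} found in {directory}")


def _read_lines(path: Path) -> list[str]:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        return [line.rstrip("\n") for line in handle if line.strip()]


def read_counts_mtx(directory_path: str | Path) -> CountMatrix:
    """Read a CellRanger-style Matrix Market triplet directory.

    Expects ``matrix.mtx[.gz]`` plus ``barcodes.tsv[.gz]`` and
    ``features.tsv[.gz]`` (or ``genes.tsv``). The returned matrix is always
    features x barcodes regardless of on-disk orientation.
    """
    directory = Path(directory_path)
    if not directory.is_dir():
        raise FileNotFoundError(f"no such directory: {directory}")
    mtx_path = _find_file(directory, ("matrix.mtx", "matrix.mtx.gz"))
    bc_path = _find_file(directory, ("barcodes.tsv", "barcodes.tsv.gz"))
    feat_path = _find_file(directory, ("features.tsv", "features.tsv.gz", "genes.tsv", "genes.tsv.gz"))
    barcodes = _read_lines(bc_path)
    feature_rows = [line.split("\t") for line in _read_lines(feat_path)]
    # CellRanger features.tsv: id, name, feature type; prefer the display name
    features = [row[1] if len(row) > 1 else row[0] for row in feature_rows]
    mat = mmread(str(mtx_path))
    if np.issubdtype(mat.dtype, np.floating) and mat.size and not np.all(np.mod(mat.data, 1) == 0):
        raise FormatError(f"{mtx_path} contains non-integer entries")
    mat = sp.csr_matrix(mat)
    if mat.shape == (len(features), len(barcodes)):
        pass
    elif mat.shape == (len(barcodes), len(features)):
        mat = mat.T.tocsr()
    else:
        raise FormatError(
            f"matrix shape {mat.shape} matches neither {len(features)} features x "
            f"{len(barcodes)} barcodes nor its transpose"
        )
    return CountMatrix(features, barcodes, mat)


def write_counts_mtx(matrix: CountMatrix, directory_path: str | Path, feature_type: str = "Antibody Capture") -> None:
    """Write a CountMatrix as a Matrix Market triplet directory (uncompressed)."""
    directory = Path(directory_path)
    directory.mkdir(parents=True, exist_ok=True)
    mmwrite(str(directory / "matrix.mtx"), matrix.counts.tocoo(), field="integer")
    (directory / "barcodes.tsv").write_text("".join(b + "\n" for b in matrix.barcode_ids))
    (directory / "features.tsv").write_text(
        "".join(f"{f}\t{f}\t{feature_type}\n" for f in matrix.feature_ids)
    )


def read_counts_csv(path: str | Path, orientation: str = "features_by_barcodes") -> CountMatrix:
    """Read a dense count CSV with a header row and leading id column."""
    if orientation not in ("features_by_barcodes", "barcodes_by_features"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    frame = pd.read_csv(path, index_col=0)
    values = frame.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise FormatError(f"{path} contains non-numeric entries")
    if np.any(values < 0):
        raise FormatError(f"{path} contains negative entries")
    if not np.all(np.mod(values, 1) == 0):
        raise FormatError(f"{path} contains non-integer entries")
    if orientation == "barcodes_by_features":
        frame = frame.T
    return CountMatrix.from_frame(frame)


def write_counts_csv(matrix: CountMatrix, path: str | Path) -> None:
    matrix.to_frame().rename_axis("feature").to_csv(path)


def read_metadata_csv(path: str | Path) -> pd.DataFrame:
    """Per-barcode metadata CSV (column ``barcode`` as key)."""
    frame = pd.read_csv(path)
    if "barcode" not in frame.columns:
        raise FormatError(f"{path} lacks a 'barcode' column")
    return frame.set_index("barcode")
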