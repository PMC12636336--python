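"""Tabular I/O and shared coordinate conventions.

All genomic coordinates are 1-based and inclusive internally.  The only
place 0-based arithmetic occurs is in the BED reader, which converts
half-open 0-based intervals on input.

Marker identifiers follow the ``chrNN_POS`` convention (e.g.
``chr04_465458``), where POS is the 1-based bp position of the variant.
Haplotype (founder-of-origin) labels are integers 1..8 on disk, with
missing cells written as ``NA``; internally missing labels are stored
as 0 in an int8 matrix.
"""

from __future__ import annotations

import io
import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING_LABEL = 0
_MARKER_RE = re.compile(r"^(?P<chrom>chr[0-9A-Za-z]+)_(?P<pos>\d+)$")


def marker_id(chrom: str, pos: int) -> str:
    """Canonical marker id for a chromosome/position pair."""
    return f"{chrom}_{int(pos)}"


def parse_marker_id(mid: str) -> tuple[str, int]:
    m = _MARKER_RE.match(mid)
    if m is None:
        raise ValueError(f"marker id {mid!r} does not match 'chrNN_POS'")
    return m.group("chrom"), int(m.group("pos"))


@dataclass
class MarkerMap:
    """Ordered marker map: id, chromosome, 1-based position, scaffold flag.

    The scaffold flag marks membership of the evenly spaced subset used
    for genome-wide scans; the full set is used for fine-mapping.
    """

    frame: pd.DataFrame  # columns: marker_id, chrom, pos, scaffold

    def __post_init__(self) -> None:
        required = ["marker_id", "chrom", "pos", "scaffold"]
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise ValueError(f"marker map missing columns {missing}")
        f = self.frame.reset_index(drop=True)
        f["pos"] = f["pos"].astype(np.int64)
        f["scaffold"] = f["scaffold"].astype(bool)
        if f["marker_id"].duplicated().any():
            dup = f.loc[f["marker_id"].duplicated(), "marker_id"].iloc[0]
            raise ValueError(f"duplicate marker id {dup!r}")
        for chrom, sub in f.groupby("chrom", sort=False):
            d = np.diff(sub["pos"].to_numpy())
            if (d <= 0).any():
                raise ValueError(
                    f"positions not strictly increasing on {chrom}"
                )
        for mid, chrom, pos in zip(f["marker_id"], f["chrom"], f["pos"]):
            c, p = parse_marker_id(mid)
            if c != chrom or p != pos:
                raise ValueError(
                    f"marker id {mid!r} inconsistent with map entry "
                    f"({chrom}, {pos})"
                )
        self.frame = f
        self._index = {m: i for i, m in enumerate(f["marker_id"])}

    @classmethod
    def from_positions(
        cls,
        chroms: Sequence[str],
        positions: Sequence[int],
        scaffold: Sequence[bool] | None = None,
    ) -> "MarkerMap":
        chroms = list(chroms)
        positions = [int(p) for p in positions]
        if scaffold is None:
            scaffold = [True] * len(chroms)
        ids = [marker_id(c, p) for c, p in zip(chroms, positions)]
        return cls(
            pd.DataFrame(
                {
                    "marker_id": ids,
                    "chrom": chroms,
                    "pos": positions,
                    "scaffold": list(scaffold),
                }
            )
        )

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def ids(self) -> np.ndarray:
        return self.frame["marker_id"].to_numpy()

    @property
    def chrom(self) -> np.ndarray:
        return self.frame["chrom"].to_numpy()

    @property
    def pos(self) -> np.ndarray:
        return self.frame["pos"].to_numpy()

    @property
    def scaffold(self) -> np.ndarray:
        return self.frame["scaffold"].to_numpy()

    def index_of(self, mid: str) -> int:
        try:
            return self._index[mid]
        except KeyError:
            raise KeyError(f"unknown marker id {mid!r}") from None

    def chrom_indices(self, chrom: str) -> np.ndarray:
        return np.flatnonzero(self.chrom == chrom)

    def write(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "MarkerMap":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class HaplotypeMatrix:
    """Strains x markers founder-of-origin labels (1..n_founders, 0=missing)."""

    strains: np.ndarray
    labels: np.ndarray  # int8, shape (n_strains, n_markers)
    markers: MarkerMap
    n_founders: int = 8

    def __post_init__(self) -> None:
        self.strains = np.asarray(self.strains, dtype=object)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.shape != (len(self.strains), len(self.markers)):
            raise ValueError(
                f"label matrix shape {self.labels.shape} inconsistent with "
                f"{len(self.strains)} strains x {len(self.markers)} markers"
            )
        bad = (self.labels < 0) | (self.labels > self.n_founders)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"label {self.labels[i, j]} at strain {self.strains[i]!r}, "
                f"marker {self.markers.ids[j]!r} outside 1..{self.n_founders}"
            )
        if pd.Series(self.strains).duplicated().any():
            raise ValueError("duplicate strain ids")

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    def strain_index(self, strain_ids: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.strains)}
        return np.array([lookup[s] for s in strain_ids], dtype=np.intp)

    def column(self, mid: str) -> np.ndarray:
        return self.labels[:, self.markers.index_of(mid)]

    def subset_strains(self, idx: np.ndarray) -> "HaplotypeMatrix":
        return HaplotypeMatrix(
            self.strains[idx], self.labels[idx], self.markers, self.n_founders
        )

    def write(self, path) -> None:
        df = pd.DataFrame(
            self.labels.astype(object), columns=self.markers.ids
        )
        df = df.mask(df == MISSING_LABEL)
        df.insert(0, "strain", self.strains)
        df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_haplotypes(path, markers: MarkerMap) -> HaplotypeMatrix:
    """Read a strains x markers TSV of founder labels against a marker map.

    The header row must contain marker ids known to ``markers``; cells are
    integers 1..8 or ``NA``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"strain": str})
    if "strain" not in df.columns:
        raise ValueError("haplotype table must have a 'strain' column")
    cols = [c for c in df.columns if c != "strain"]
    for c in cols:
        if c not in markers._index:
            raise ValueError(f"unknown marker id {c!r} in haplotype table")
    order = sorted(cols, key=markers.index_of)
    if [markers.index_of(c) for c in order] != list(range(len(markers))):
        raise ValueError("haplotype table does not cover the marker map")
    if df["strain"].duplicated().any():
        dup = df.loc[df["strain"].duplicated(), "strain"].iloc[0]
        raise ValueError(f"duplicate strain id {dup!r}")
    vals = df[order].to_numpy(dtype=float)
    labels = np.where(np.isnan(vals), MISSING_LABEL, vals)
    if not np.array_equal(labels, np.round(labels)):
        raise ValueError("non-integer haplotype label")
    labels = labels.astype(np.int8)
    bad = (labels < 0) | (labels > 8)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"label {vals[i, j]:g} outside 1..8 at strain "
            f"{df['strain'].iloc[i]!r}, marker {order[j]!r}"
        )
    return HaplotypeMatrix(df["strain"].to_numpy(object), labels, markers)


@dataclass
class PhenotypeTable:
    """Replicate-level or aggregated growth values.

    Required columns: strain, condition, timepoint, value.  Optional:
    replicate, plate, batch, well_row (1..8), well_col (1..12).  Raw
    values are patch areas in pixels (nonnegative); normalized or
    residualized values are unitless and may take any sign.
    """

    frame: pd.DataFrame
    meta: dict = field(default_factory=dict)

    REQUIRED = ("strain", "condition", "timepoint", "value")
    OPTIONAL = ("replicate", "plate", "batch", "well_row", "well_col")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns {missing}")
        f = self.frame.reset_index(drop=True)
        key = ["strain", "condition", "timepoint"]
        if "replicate" in f.columns:
            key.append("replicate")
        if f.duplicated(subset=key).any():
            raise ValueError(f"duplicate measurement for key {key}")
        self.frame = f

    def with_values(self, values: np.ndarray, **meta) -> "PhenotypeTable":
        f = self.frame.copy()
        f["value"] = values
        return PhenotypeTable(f, {**self.meta, **meta})

    def strain_values(
        self, condition: str, timepoint, strains: Sequence[str]
    ) -> np.ndarray:
        """Per-strain values (aggregated table), aligned to ``strains``."""
        sub = self.frame[
            (self.frame["condition"] == condition)
            & (self.frame["timepoint"] == timepoint)
        ]
        if "replicate" in sub.columns and sub["strain"].duplicated().any():
            sub = sub.groupby("strain", as_index=False)["value"].mean()
        series = sub.set_index("strain")["value"]
        return series.reindex(strains).to_numpy(dtype=float)

    def write(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def read(cls, path, column_map: Mapping[str, str] | None = None
             ) -> "PhenotypeTable":
        """Read a TSV; ``column_map`` maps on-disk names to canonical ones.

        The column map absorbs naming differences in externally deposited
        tables so they load without manual editing.
        """
        df = pd.read_csv(path, sep="\t", na_values=["NA"])
        if column_map:
            df = df.rename(columns=dict(column_map))
        return cls(df)


@dataclass
class GeneAnnotation:
    """ORF coordinates: gene, chrom, start, end (1-based inclusive), strand."""

    frame: pd.DataFrame  # columns: gene, chrom, start, end, strand

    def __post_init__(self) -> None:
        f = self.frame.reset_index(drop=True)
        required = ["gene", "chrom", "start", "end", "strand"]
        missing = [c for c in required if c not in f.columns]
        if missing:
            raise ValueError(f"gene annotation missing columns {missing}")
        if (f["start"] > f["end"]).any():
            raise ValueError("gene with start > end")
        if not f["strand"].isin(["+", "-"]).all():
            raise ValueError("strand must be '+' or '-'")
        self.frame = f

    def on_chrom(self, chrom: str) -> pd.DataFrame:
        return self.frame[self.frame["chrom"] == chrom]

    def write_gff3(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for r in self.frame.itertuples(index=False):
                fh.write(
                    f"{r.chrom}\tfunnelqtl\tgene\t{r.start}\t{r.end}\t.\t"
                    f"{r.strand}\t.\tID={r.gene};Name={r.gene}\n"
                )


def read_genes(path) -> GeneAnnotation:
    """Read gene annotations from GFF3 (``.gff``/``.gff3``) or BED6 (``.bed``).

    BED input is 0-based half-open and converted to 1-based inclusive.
    """
    path = str(path)
    if path.endswith((".gff", ".gff3")):
        rows = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 9 or parts[2] not in ("gene", "ORF"):
                    continue
                chrom, _, _, start, end, _, strand, _, attrs = parts[:9]
                if strand not in ("+", "-"):
                    raise ValueError(f"missing strand for line: {line!r}")
                name = None
                for kv in attrs.split(";"):
                    k, _, v = kv.partition("=")
                    if k in ("Name", "ID", "gene_id"):
                        name = v
                        if k == "Name":
                            break
                rows.append(
                    dict(gene=name, chrom=chrom, start=int(start),
                         end=int(end), strand=strand)
                )
        return GeneAnnotation(pd.DataFrame(rows))
    if path.endswith(".bed"):
        df = pd.read_csv(
            path, sep=r"\s+", header=None,
            names=["chrom", "start", "end", "gene", "score", "strand"],
        )
        if df["strand"].isna().any():
            raise ValueError("BED line missing strand")
        df["start"] = df["start"].astype(int) + 1  # 0-based -> 1-based
        df["end"] = df["end"].astype(int)
        return GeneAnnotation(
            df[["gene", "chrom", "start", "end", "strand"]]
        )
    raise ValueError(f"unrecognized gene annotation extension: {path}")


def write_results(obj, path) -> None:
    """Serialize a pipeline product to TSV (tabular) or JSON (nested).

    Column order is deterministic and floats are written at full
    precision, so two writes of the same object are byte-identical.
    """
    if isinstance(obj, pd.DataFrame):
        obj.to_csv(path, sep="\t", index=False, na_rep="NA",
                   float_format="%.17g")
        return
    frame = getattr(obj, "to_frame", None)
    if frame is not None:
        df = frame()
        df.to_csv(path, sep="\t", index=False, na_rep="NA",
                  float_format="%.17g")
        return
    record = getattr(obj, "to_dict", None)
    if record is not None:
        with open(path, "w") as fh:
            json.dump(record(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        return
    raise TypeError(f"cannot serialize object of type {type(obj).__name__}")
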