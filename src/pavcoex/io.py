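"""Readers and writers for the pipeline's standard formats.

No analysis logic lives here. Coordinates are 1-based inclusive (GFF3
convention) everywhere; a read/write cycle preserves them exactly.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
import numpy as np
import pandas as pd
from pyfaidx import Fasta

log = logging.getLogger(__name__)

IUPAC_NT = set("ACGTRYSWKMBDHVN")


# ---------------------------------------------------------------------------
# counts + sample sheet

@dataclass
class CountsMatrix:
    """Integer gene x sample read counts with per-sample library sizes."""

    gene_ids: pd.Index
    sample_ids: pd.Index
    counts: np.ndarray  # (n_genes, n_samples) int64

    def __post_init__(self) -> None:
        self.gene_ids = pd.Index(self.gene_ids)
        self.sample_ids = pd.Index(self.sample_ids)
        if self.gene_ids.has_duplicates:
            dup = self.gene_ids[self.gene_ids.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        if self.sample_ids.has_duplicates:
            dup = self.sample_ids[self.sample_ids.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be integers")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def lib_sizes(self) -> np.ndarray:
        """Per-sample column sums (reads)."""
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    def reorder_samples(self, sample_ids: Iterable[str]) -> "CountsMatrix":
        idx = pd.Index(sample_ids)
        pos = self.sample_ids.get_indexer(idx)
        if (pos < 0).any():
            missing = idx[pos < 0][0]
            raise ValueError(f"sample {missing!r} not in counts matrix")
        return CountsMatrix(self.gene_ids, idx, self.counts[:, pos])


def read_counts(path, *, allow_fractional: bool = False) -> CountsMatrix:
    """Read a genes x samples TSV (header = sample ids, first column = gene ids).

    Counts must be integers. With ``allow_fractional=True``, fractional
    estimated counts (e.g. from a quantifier) are rounded half-to-even with a
    logged warning instead of raising.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = df.columns[[not np.issubdtype(t, np.number) for t in df.dtypes]][0]
        raise ValueError(f"non-numeric counts in column {bad!r}")
    frac = values != np.floor(values)
    if frac.any():
        if not allow_fractional:
            i, j = np.argwhere(frac)[0]
            raise ValueError(
                f"non-integer count {values[i, j]} for gene {df.index[i]!r}, "
                f"sample {df.columns[j]!r}"
            )
        log.warning(
            "%d fractional counts in %s rounded half-to-even", int(frac.sum()), path
        )
        values = np.rint(values)
    return CountsMatrix(df.index, df.columns, values.astype(np.int64))


def read_sample_sheet(path) -> pd.DataFrame:
    """Read a sample sheet CSV with columns sample_id, strain_id, replicate."""
    df = pd.read_csv(path, dtype={"sample_id": str, "strain_id": str})
    return validate_sample_sheet(df)


def validate_sample_sheet(df: pd.DataFrame) -> pd.DataFrame:
    required = {"sample_id", "strain_id", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample id in sheet: {dup!r}")
    if (df["replicate"].astype(int) < 1).any():
        raise ValueError("replicate numbers must be >= 1")
    reps = df.groupby("strain_id").size()
    if (reps < 2).any():
        bad = reps[reps < 2].index[0]
        raise ValueError(f"strain {bad!r} has fewer than 2 replicates")
    return df.reset_index(drop=True)


def read_expression_inputs(counts_path, sample_sheet_path, *,
                           allow_fractional: bool = False):
    """Read and cross-validate counts + sample sheet.

    Returns the counts with samples ordered as in the sheet.
    """
    counts = read_counts(counts_path, allow_fractional=allow_fractional)
    sheet = read_sample_sheet(sample_sheet_path)
    sheet_ids = set(sheet["sample_id"])
    count_ids = set(counts.sample_ids)
    only_counts = count_ids - sheet_ids
    if only_counts:
        raise ValueError(f"sample {sorted(only_counts)[0]!r} in counts but not in sample sheet")
    only_sheet = sheet_ids - count_ids
    if only_sheet:
        raise ValueError(f"sample {sorted(only_sheet)[0]!r} in sample sheet but not in counts")
    return counts.reorder_samples(sheet["sample_id"]), sheet


# ---------------------------------------------------------------------------
# phenotypes

def read_phenotypes(path) -> pd.DataFrame:
    """Strain-level phenotype table (CSV, one row per strain, numeric traits)."""
    df = pd.read_csv(path, dtype={"strain_id": str})
    if "strain_id" not in df.columns:
        raise ValueError("phenotype table must have a strain_id column")
    if df["strain_id"].duplicated().any():
        dup = df.loc[df["strain_id"].duplicated(), "strain_id"].iloc[0]
        raise ValueError(f"duplicate strain in phenotype table: {dup!r}")
    df = df.set_index("strain_id")
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        raise ValueError(f"non-numeric trait columns: {non_numeric}")
    return df


# ---------------------------------------------------------------------------
# annotation (GFF3)

def read_annotation(gff3_path, *, strain_id: str | None = None,
                    feature_type: str = "gene") -> pd.DataFrame:
    """Read gene features from a GFF3 file.

    Returns a DataFrame with columns strain_id, gene_id, replicon_id, start,
    end, strand; coordinates are the file's 1-based inclusive integers,
    untouched.
    """
    db = gffutils.create_db(
        str(gff3_path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="error",
    )
    records = []
    seen = set()
    for feat in db.features_of_type(feature_type):
        gene_id = feat.attributes.get("ID", [None])[0]
        if gene_id is None:
            raise ValueError(f"feature at {feat.seqid}:{feat.start} has no ID attribute")
        if gene_id in seen:
            raise ValueError(f"duplicate gene ID in annotation: {gene_id!r}")
        seen.add(gene_id)
        if feat.start > feat.end:
            raise ValueError(f"gene {gene_id!r} has start > end")
        records.append(
            (strain_id, gene_id, feat.seqid, int(feat.start), int(feat.end), feat.strand)
        )
    return pd.DataFrame(
        records, columns=["strain_id", "gene_id", "replicon_id", "start", "end", "strand"]
    )


def write_annotation(annotation: pd.DataFrame, path) -> None:
    """Write gene features as GFF3 (inverse of :func:`read_annotation`)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in annotation.itertuples(index=False):
            fh.write(
                f"{row.replicon_id}\t.\tgene\t{row.start}\t{row.end}\t.\t"
                f"{row.strand}\t.\tID={row.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# genomes (FASTA)

class GenomeStore:
    """Per-strain genome sequences with lazy, indexed access.

    Wraps one indexed FASTA per strain (record ids = replicon ids), so
    replicon lengths are available without loading sequences into memory.
    """

    def __init__(self, fasta_by_strain: Mapping[str, Path]):
        self._fastas: dict[str, Fasta] = {}
        for strain, path in fasta_by_strain.items():
            fa = Fasta(str(path), sequence_always_upper=True)
            if len(fa.keys()) == 0:
                raise ValueError(f"FASTA for strain {strain!r} has no records")
            for name in fa.keys():
                if len(fa[name]) == 0:
                    raise ValueError(f"empty record {name!r} in strain {strain!r}")
            self._fastas[strain] = fa

    @property
    def strains(self) -> list[str]:
        return list(self._fastas)

    def replicons(self, strain: str) -> list[str]:
        return list(self._fastas[strain].keys())

    def length(self, strain: str, replicon: str) -> int:
        return len(self._fastas[strain][replicon])

    def sequence(self, strain: str, replicon: str) -> str:
        seq = str(self._fastas[strain][replicon][:]).upper()
        bad = set(seq) - IUPAC_NT
        if bad:
            raise ValueError(
                f"non-IUPAC characters {sorted(bad)} in {strain}/{replicon}"
            )
        return seq


def read_genomes(fasta_by_strain: Mapping[str, Path]) -> GenomeStore:
    """Open one multi-FASTA per strain; record ids are replicon ids."""
    return GenomeStore(fasta_by_strain)


def write_fasta(sequences: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# presence matrices and gene groups

def write_presence_matrix(presence: pd.DataFrame, path) -> None:
    """Write a genes (or clusters) x strains boolean matrix as 0/1 TSV."""
    presence.astype(int).to_csv(path, sep="\t", index_label="gene_id")


def read_presence_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(bool)


def read_gene_groups(path) -> pd.DataFrame:
    """Gene-group membership table: columns group_id, strain_id, gene_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"group_id", "strain_id", "gene_id"} - set(df.columns)
    if missing:
        raise ValueError(f"gene-group table missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# results bundle

def write_results(tables: Mapping[str, pd.DataFrame], out_dir, *,
                  config=None, seed: int | None = None,
                  extra_manifest: Mapping | None = None) -> dict:
    """Write result tables as TSV plus a JSON run manifest; return the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    for name, table in tables.items():
        path = out / f"{name}.tsv"
        table.to_csv(path, sep="\t", index=isinstance(table.index, pd.Index)
                     and table.index.name is not None)
        files[name] = path.name
    manifest = {
        "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "seed": seed,
        "config_hash": config.config_hash() if config is not None else None,
        "config": config.to_dict() if config is not None else None,
        "files": files,
    }
    if extra_manifest:
        manifest.update(extra_manifest)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    if config is not None:
        log.info("thresholds used: %s", json.dumps(config.to_dict(), default=str))
    return manifest
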