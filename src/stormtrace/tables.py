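"""Count-table container shared by the amplicon and community modules."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = ["AmpliconTable", "taxon_rank_token"]

RANKS = ("domain", "phylum", "class", "genus")


def taxon_rank_token(taxon: str, rank: str) -> str:
    """Extract one rank token from a ';'-separated hierarchical label.

    Labels run domain;phylum;class;genus.  Missing ranks return ''.
    """
    parts = [p.strip() for p in taxon.split(";")]
    try:
        idx = RANKS.index(rank)
    except ValueError:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}") from None
    return parts[idx] if idx < len(parts) else ""


@dataclass
class AmpliconTable:
    """Sequence type x sample count matrix with sequences, taxa and metadata.

    ``counts`` rows are sequence-type ids, columns sample ids.  ``sample_meta``
    is indexed by sample id and must carry ``dna_yield`` (ng DNA per ml
    water); simulated tables also carry ``true_f`` (ground-truth
    contamination fraction) and ``ecoli_conc``.
    """

    counts: pd.DataFrame
    sequences: pd.Series
    taxa: pd.Series
    sample_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate sequence-type ids")
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        for name, s in (("sequences", self.sequences), ("taxa", self.taxa)):
            missing = self.counts.index.difference(s.index)
            if len(missing):
                raise ValueError(f"{name} missing for rows {list(missing)[:5]}")
        if len(self.sample_meta):
            missing = self.counts.columns.difference(self.sample_meta.index)
            if len(missing):
                raise ValueError(f"sample_meta missing for samples {list(missing)[:5]}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def row_ids(self) -> list[str]:
        return list(self.counts.index)

    def relative_abundance(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=0)
        if (totals == 0).any():
            zero = totals.index[totals == 0].tolist()
            raise ValueError(f"samples with zero total counts: {zero}")
        return self.counts / totals

    def rank_tokens(self, rank: str) -> pd.Series:
        return self.taxa.loc[self.counts.index].map(
            lambda t: taxon_rank_token(t, rank)
        )

    def aggregate_by_rank(self, rank: str) -> pd.DataFrame:
        """Counts summed over sequence types sharing a rank token."""
        tokens = self.rank_tokens(rank)
        return self.counts.groupby(tokens).sum()

    # ----------------------------------------------------------- TSV I/O

    def to_tsv(self, counts_path: str | Path, meta_path: str | Path | None = None,
               header_comment: str | None = None) -> None:
        df = self.counts.copy()
        df.insert(0, "taxon", self.taxa.loc[df.index])
        df.insert(0, "sequence", self.sequences.loc[df.index])
        df.index.name = "sequence_type"
        with open(counts_path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            df.to_csv(fh, sep="\t")
        if meta_path is not None:
            meta = self.sample_meta.copy()
            meta.index.name = "sample_id"
            with open(meta_path, "w") as fh:
                if header_comment:
                    fh.write(f"# {header_comment}\n")
                meta.to_csv(fh, sep="\t")

    @classmethod
    def from_tsv(cls, counts_path: str | Path,
                 meta_path: str | Path | None = None) -> "AmpliconTable":
        df = pd.read_csv(counts_path, sep="\t", index_col=0, comment="#")
        sequences = df.pop("sequence")
        taxa = df.pop("taxon")
        counts = df.astype(int)
        meta = (
            pd.read_csv(meta_path, sep="\t", index_col=0, comment="#")
            if meta_path is not None
            else pd.DataFrame(index=counts.columns)
        )
        return cls(counts, sequences, taxa, meta)
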