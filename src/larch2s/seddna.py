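"""Sedimentary-DNA haplotype classification and vegetation ordination.

Two stages:

1. **Variant classification.**  Reads of the 61-bp *Larix* mitochondrial
   nad4 amplicon (primer-trimmed) are dereplicated, length/abundance
   filtered, and assigned to one of two mitochondrial variants — the
   "*L. sibirica*"-variant or the "*L. gmelinii*"-variant — by the base at
   the single diagnostic SNP (locus position 1433), tolerating a small
   number of background mismatches elsewhere.  Per sediment sample this
   yields variant counts, proportions over assigned reads, and a
   dominance call (a variant if it holds >= 90% of assigned reads with at
   least 10 assigned reads; "mixed" otherwise; "none" below the depth
   gate).

2. **Ordination.**  DNA-metabarcoding and pollen count tables are
   aggregated to genus, filtered to dominant taxa (>= 0.5% in >= 2
   samples), converted to square-rooted percentages, and ordinated with
   PCA; PC1 is sign-oriented by the *Larix* loading so "more larch" is a
   consistent direction, and the DNA and pollen PC1 series are compared
   by correlation on matched samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy import stats
from sklearn.decomposition import PCA

from .species import GMELINII, SIBIRICA

__all__ = [
    "AmpliconReference",
    "ReadRecord",
    "SampleVariantProfile",
    "TaxaTable",
    "OrdinationResult",
    "dereplicate_and_filter",
    "classify_read",
    "profile_sample",
    "call_dominance",
    "prepare_taxa_table",
    "pca_first_component",
    "compare_proxies",
]

UNASSIGNED = "unassigned"
AMPLICON_LEN = 61
_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class AmpliconReference:
    """Primer-trimmed 61-nt amplicon reference with one diagnostic SNP.

    ``sequence`` is the shared backbone (the base at
    ``diagnostic_offset`` is ignored during mismatch counting);
    ``allele_map`` maps the two diagnostic bases to the two variants.
    """

    sequence: str
    diagnostic_offset: int
    allele_map: Mapping[str, str]

    def __post_init__(self):
        if len(self.sequence) != AMPLICON_LEN:
            raise ValueError(f"reference must be {AMPLICON_LEN} nt, got {len(self.sequence)}")
        if not 0 <= self.diagnostic_offset < AMPLICON_LEN:
            raise ValueError("diagnostic_offset out of range")
        if len(self.allele_map) != 2 or len(set(self.allele_map.values())) != 2:
            raise ValueError("allele_map must map exactly 2 bases to 2 distinct variants")
        object.__setattr__(self, "sequence", self.sequence.upper())
        object.__setattr__(self, "allele_map", dict(self.allele_map))

    @classmethod
    def from_fasta(cls, path) -> "AmpliconReference":
        """Build from a 2-record FASTA (one sequence per variant, ids
        containing the variant names); the diagnostic offset is the
        single position at which the two records differ."""
        recs = list(SeqIO.parse(str(path), "fasta"))
        if len(recs) != 2:
            raise ValueError("reference FASTA must contain exactly 2 records")
        seqs = [str(r.seq).upper() for r in recs]
        if len(seqs[0]) != len(seqs[1]):
            raise ValueError("reference sequences differ in length")
        diffs = [i for i, (a, b) in enumerate(zip(*seqs)) if a != b]
        if len(diffs) != 1:
            raise ValueError(f"reference sequences must differ at exactly 1 position, found {len(diffs)}")
        offset = diffs[0]
        allele_map = {}
        for rec, seq in zip(recs, seqs):
            ident = rec.id.lower() + rec.description.lower()
            variant = SIBIRICA if SIBIRICA in ident else GMELINII if GMELINII in ident else None
            if variant is None:
                raise ValueError(f"cannot infer variant from record id {rec.id!r}")
            allele_map[seq[offset]] = variant
        return cls(seqs[0], offset, allele_map)

    def variant_sequence(self, variant: str) -> str:
        """The full 61-nt sequence carrying ``variant``'s diagnostic base."""
        base = {v: k for k, v in self.allele_map.items()}[variant]
        s = list(self.sequence)
        s[self.diagnostic_offset] = base
        return "".join(s)


def default_reference(seed: int = 1433) -> AmpliconReference:
    """A synthetic stand-in for the real nad4 amplicon reference (the
    deposited sequence data is not redistributed here): a deterministic
    61-nt backbone with the diagnostic A/G SNP at offset 30."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    seq = "".join(rng.choice(bases, size=AMPLICON_LEN))
    seq = seq[:30] + "A" + seq[31:]
    return AmpliconReference(seq, 30, {"A": SIBIRICA, "G": GMELINII})


@dataclass(frozen=True)
class ReadRecord:
    """A dereplicated read: one sequence with its multiplicity."""

    sequence: str
    count: int
    sample_id: str = ""

    def __post_init__(self):
        if self.count < 1:
            raise ValueError("count must be >= 1")
        seq = self.sequence.upper()
        if set(seq) - _ALPHABET:
            raise ValueError(f"sequence contains non-ACGTN characters: {sorted(set(seq) - _ALPHABET)}")
        object.__setattr__(self, "sequence", seq)


@dataclass
class SampleVariantProfile:
    """Per-sample variant counts, proportions over assigned reads, and
    the dominance call."""

    sample_id: str
    counts: dict[str, int]
    depth_cm: float | None = None
    age_calbp: float | None = None
    dominance_call: str = "none"

    @property
    def assigned(self) -> int:
        return self.counts.get(SIBIRICA, 0) + self.counts.get(GMELINII, 0)

    @property
    def proportions(self) -> dict[str, float]:
        a = self.assigned
        if a == 0:
            return {SIBIRICA: np.nan, GMELINII: np.nan}
        return {sp: self.counts.get(sp, 0) / a for sp in (SIBIRICA, GMELINII)}


@dataclass
class TaxaTable:
    """Samples x taxa count matrix with per-sample metadata.

    ``counts`` is a DataFrame (rows = samples, columns = taxa);
    ``meta`` carries depth_cm / age_calbp / proxy per sample;
    ``genus_map`` maps each taxon to its genus (default: first word of
    the taxon name).
    """

    counts: pd.DataFrame
    meta: pd.DataFrame = None
    genus_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("taxa counts must be non-negative")
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate taxon ids")
        if self.meta is None:
            self.meta = pd.DataFrame(index=self.counts.index)
        for taxon in self.counts.columns:
            self.genus_map.setdefault(taxon, str(taxon).split()[0])


@dataclass
class OrdinationResult:
    """PC scores per sample, explained-variance proportions, loadings."""

    scores: pd.Series
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame


# ---------------------------------------------------------------------
# Read processing
# ---------------------------------------------------------------------

def _iter_sequences(reads, fmt: str | None):
    if isinstance(reads, (str, Path)):
        path = str(reads)
        if fmt is None:
            fmt = "fastq" if path.endswith((".fastq", ".fq")) else "fasta"
        reads = SeqIO.parse(path, fmt)
    for i, rec in enumerate(reads):
        if isinstance(rec, str):
            yield i, rec
        elif hasattr(rec, "seq"):
            yield i, str(rec.seq)
        else:
            raise ValueError(f"unparseable read record at index {i}: {rec!r}")


def dereplicate_and_filter(
    reads,
    min_len: int = AMPLICON_LEN,
    max_len: int = AMPLICON_LEN,
    min_count: int = 2,
    sample_id: str = "",
    fmt: str | None = None,
) -> list[ReadRecord]:
    """Merge identical sequences (summing multiplicities), drop records
    outside ``[min_len, max_len]`` or below ``min_count``; output sorted
    by count (desc) then sequence, so it is order-independent.

    ``reads`` may be a FASTA/FASTQ path, an iterable of Bio.SeqRecord, or
    an iterable of plain sequence strings.
    """
    tally: dict[str, int] = {}
    for i, seq in _iter_sequences(reads, fmt):
        seq = seq.upper()
        if set(seq) - _ALPHABET:
            raise ValueError(f"unparseable read record at index {i}: non-ACGTN sequence")
        tally[seq] = tally.get(seq, 0) + 1
    records = [
        ReadRecord(seq, n, sample_id)
        for seq, n in tally.items()
        if min_len <= len(seq) <= max_len and n >= min_count
    ]
    records.sort(key=lambda r: (-r.count, r.sequence))
    return records


def classify_read(record: ReadRecord | str, ref: AmpliconReference, max_mismatch: int = 3) -> str:
    """Assign a read to a variant by its diagnostic base, requiring exact
    amplicon length and at most ``max_mismatch`` background mismatches
    (the diagnostic position is not counted); anything else — including N
    at the diagnostic position — is ``unassigned``."""
    seq = record.sequence if isinstance(record, ReadRecord) else record.upper()
    if len(seq) != AMPLICON_LEN:
        return UNASSIGNED
    base = seq[ref.diagnostic_offset]
    if base not in ref.allele_map:
        return UNASSIGNED
    mism = sum(
        1
        for i, (a, b) in enumerate(zip(seq, ref.sequence))
        if i != ref.diagnostic_offset and a != b
    )
    if mism > max_mismatch:
        return UNASSIGNED
    return ref.allele_map[base]


def profile_sample(
    records: Sequence[ReadRecord],
    ref: AmpliconReference,
    max_mismatch: int = 3,
    dom_threshold: float = 0.9,
    min_assigned: int = 10,
    depth_cm: float | None = None,
    age_calbp: float | None = None,
) -> SampleVariantProfile:
    """Aggregate classified reads (with multiplicities) for one sample
    and attach the dominance call."""
    sample_ids = {r.sample_id for r in records}
    if len(sample_ids) > 1:
        raise ValueError(f"records span multiple samples: {sorted(sample_ids)}")
    counts = {SIBIRICA: 0, GMELINII: 0, UNASSIGNED: 0}
    for r in records:
        counts[classify_read(r, ref, max_mismatch)] += r.count
    prof = SampleVariantProfile(
        sample_id=next(iter(sample_ids), ""),
        counts=counts,
        depth_cm=depth_cm,
        age_calbp=age_calbp,
    )
    prof.dominance_call = call_dominance(prof, dom_threshold, min_assigned)
    return prof


def call_dominance(profile: SampleVariantProfile, dom_threshold: float = 0.9,
                   min_assigned: int = 10) -> str:
    """"none" below the read-depth gate; a variant when its proportion of
    assigned reads reaches ``dom_threshold``; "mixed" otherwise."""
    if dom_threshold <= 0.5:
        raise ValueError("dom_threshold must exceed 0.5 (otherwise ambiguous)")
    if profile.assigned < min_assigned:
        return "none"
    props = profile.proportions
    for sp in (SIBIRICA, GMELINII):
        if props[sp] >= dom_threshold:
            return sp
    return "mixed"


def profiles_to_frame(profiles: Sequence[SampleVariantProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        props = p.proportions
        rows.append(
            {
                "sample_id": p.sample_id,
                "depth_cm": p.depth_cm,
                "age_calbp": p.age_calbp,
                "count_sibirica": p.counts.get(SIBIRICA, 0),
                "count_gmelinii": p.counts.get(GMELINII, 0),
                "count_unassigned": p.counts.get(UNASSIGNED, 0),
                "prop_sibirica": props[SIBIRICA],
                "prop_gmelinii": props[GMELINII],
                "dominance_call": p.dominance_call,
            }
        )
    return pd.DataFrame(rows)


_META_COLS = ("depth_cm", "age_calbp", "proxy")


def read_taxa_tsv(path) -> TaxaTable:
    """Read a samples-as-rows TSV with metadata columns depth_cm,
    age_calbp, proxy followed by taxa count columns."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta_cols = [c for c in _META_COLS if c in df.columns]
    meta = df[meta_cols]
    counts = df.drop(columns=meta_cols)
    return TaxaTable(counts=counts, meta=meta)


def write_taxa_tsv(table: TaxaTable, path) -> None:
    meta = table.meta.reindex(table.counts.index)
    df = pd.concat([meta, table.counts], axis=1)
    df.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------
# Ordination
# ---------------------------------------------------------------------

def prepare_taxa_table(table: TaxaTable, min_pct: float = 0.5, min_samples: int = 2) -> pd.DataFrame:
    """Genus aggregation -> per-sample percentages -> dominant-taxon
    filter (>= ``min_pct`` % in >= ``min_samples`` samples) -> square
    root.  Returns the transformed samples x genera matrix."""
    counts = table.counts
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        bad = totals.index[totals == 0][0]
        raise ValueError(f"sample {bad!r} has zero total count")
    genus = counts.T.groupby([table.genus_map[t] for t in counts.columns]).sum().T
    pct = genus.div(genus.sum(axis=1), axis=0) * 100.0
    keep = (pct >= min_pct).sum(axis=0) >= min_samples
    return np.sqrt(pct.loc[:, keep])


def pca_first_component(matrix: pd.DataFrame, orient_taxon: str = "Larix") -> OrdinationResult:
    """PCA on the column-centred (unscaled) matrix; PC1 sign is oriented
    so that ``orient_taxon``'s loading is non-negative."""
    if matrix.shape[0] < 3:
        raise ValueError("need at least 3 samples for ordination")
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 taxa for ordination")
    n_comp = min(matrix.shape[0] - 1, matrix.shape[1])
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(matrix.values)
    loadings = pca.components_.T  # taxa x components
    if orient_taxon in matrix.columns:
        k = list(matrix.columns).index(orient_taxon)
        if loadings[k, 0] < 0:
            scores[:, 0] *= -1.0
            loadings[:, 0] *= -1.0
    return OrdinationResult(
        scores=pd.Series(scores[:, 0], index=matrix.index, name="PC1"),
        explained_variance_ratio=pca.explained_variance_ratio_,
        loadings=pd.DataFrame(
            loadings, index=matrix.columns,
            columns=[f"PC{i+1}" for i in range(n_comp)],
        ),
    )


def compare_proxies(dna_scores: pd.Series, pollen_scores: pd.Series,
                    matched: Sequence[tuple] | None = None) -> dict:
    """Pearson and Spearman correlation of the two PC1 series over
    matched samples (by shared index when ``matched`` is None), plus the
    paired series for stratigraphic plotting."""
    if matched is None:
        common = dna_scores.index.intersection(pollen_scores.index)
        pairs = [(s, s) for s in common]
    else:
        pairs = list(matched)
    if len(pairs) < 3:
        raise ValueError("need at least 3 matched sample pairs")
    d = np.array([dna_scores.loc[a] for a, _ in pairs], dtype=float)
    p = np.array([pollen_scores.loc[b] for _, b in pairs], dtype=float)
    pearson = stats.pearsonr(d, p)
    spearman = stats.spearmanr(d, p)
    return {
        "pearson_r": float(pearson.statistic),
        "pearson_p": float(pearson.pvalue),
        "spearman_rho": float(spearman.statistic),
        "spearman_p": float(spearman.pvalue),
        "paired": pd.DataFrame({"dna_pc1": d, "pollen_pc1": p},
                               index=[a for a, _ in pairs]),
    }
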