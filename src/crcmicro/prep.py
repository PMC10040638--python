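"""Reading, validation and preprocessing of ASV count tables.

The pipeline's substrate is a trio of tab-separated tables:

* counts — rows are ASV ids, columns are sample ids, integer read counts
  (held in memory transposed, as a samples x taxa :class:`pandas.DataFrame`);
* metadata — one row per sample with ``group`` (BP or tumor stage T1-T4),
  ``age`` in years and ``gender``;
* taxonomy — ASV id to a semicolon-delimited 7-rank SILVA-style lineage
  (``d__;p__;c__;o__;f__;g__;s__``), ranks possibly unassigned.

Preprocessing follows the usual amplicon post-denoising cascade: remove
organellar/non-bacterial lineages, drop rare ASVs seen in too few samples,
rarefy every sample to a common read depth (without replacement), then
convert to relative abundance and/or collapse to a higher taxonomic rank.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import InputError

logger = logging.getLogger(__name__)

GROUPS = ("BP", "T1", "T2", "T3", "T4")
STAGES = ("T1", "T2", "T3", "T4")

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
RANK_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")

DEFAULT_EXCLUDED_LINEAGES = frozenset(
    {"Mitochondria", "Chloroplast", "Archaea", "Eukaryota"}
)


# ---------------------------------------------------------------------------
# readers / writers


def parse_lineage(lineage: str) -> list[str]:
    """Split a semicolon-delimited lineage into 7 rank fields.

    SILVA-style ``d__`` prefixes are stripped; missing trailing ranks become
    empty strings, so the result always has exactly 7 entries.
    """
    fields = [f.strip() for f in str(lineage).split(";")]
    if len(fields) > len(RANKS):
        raise InputError(f"lineage has more than 7 ranks: {lineage!r}")
    out = []
    for i in range(len(RANKS)):
        field = fields[i] if i < len(fields) else ""
        prefix = RANK_PREFIXES[i]
        if field.startswith(prefix):
            field = field[len(prefix):]
        out.append(field)
    return out


def taxonomy_frame(lineages: pd.Series) -> pd.DataFrame:
    """Expand a Series of lineage strings into a taxon x rank DataFrame.

    Keeps the raw string in a ``lineage`` column alongside the 7 rank columns.
    """
    parsed = [parse_lineage(v) for v in lineages]
    tax = pd.DataFrame(parsed, index=lineages.index, columns=list(RANKS))
    tax["lineage"] = lineages.astype(str).values
    return tax


def read_tables(counts_path, metadata_path, taxonomy_path):
    """Read and reconcile the counts / metadata / taxonomy TSV trio.

    Sample sets of counts and metadata are intersected (mismatches logged);
    likewise the taxon sets of counts and taxonomy.  Returns
    ``(counts, metadata, taxonomy)`` with counts as samples x taxa.
    """
    raw = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts = raw.T  # file stores taxa as rows
    if counts.index.duplicated().any() or counts.columns.duplicated().any():
        raise InputError("duplicate sample or taxon ids in counts table")
    counts = counts.astype(np.int64)
    if (counts.values < 0).any():
        raise InputError("negative counts in counts table")

    meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
    if meta.index.duplicated().any():
        raise InputError("duplicate sample ids in metadata")
    validate_metadata(meta)

    taxref = pd.read_csv(taxonomy_path, sep="\t", index_col=0)
    if taxref.index.duplicated().any():
        raise InputError("duplicate taxon ids in taxonomy")
    lineage_col = taxref.columns[0]
    taxonomy = taxonomy_frame(taxref[lineage_col])

    samples = counts.index.intersection(meta.index)
    if len(samples) == 0:
        raise InputError("no samples shared between counts and metadata")
    dropped = counts.index.difference(samples).tolist() + meta.index.difference(
        samples
    ).tolist()
    if dropped:
        logger.warning("dropping %d unmatched samples: %s", len(dropped), dropped)

    taxa = counts.columns.intersection(taxonomy.index)
    if len(taxa) == 0:
        raise InputError("no taxa shared between counts and taxonomy")
    missing = counts.columns.difference(taxa)
    if len(missing):
        logger.warning("dropping %d taxa without taxonomy", len(missing))

    counts = counts.loc[samples, taxa]
    meta = meta.loc[samples]
    taxonomy = taxonomy.loc[taxa]
    return counts, meta, taxonomy


def validate_metadata(meta: pd.DataFrame) -> None:
    for col in ("group", "age", "gender"):
        if col not in meta.columns:
            raise InputError(f"metadata missing required column {col!r}")
    bad = meta.index[~meta["group"].isin(GROUPS)]
    if len(bad):
        raise InputError(
            f"invalid group label {meta.loc[bad[0], 'group']!r} for sample {bad[0]!r}"
        )
    ages = pd.to_numeric(meta["age"], errors="coerce")
    bad = meta.index[ages.isna() | (ages < 0) | (ages > 120)]
    if len(bad):
        raise InputError(f"implausible age for sample {bad[0]!r}")


def write_tables(outdir, counts, metadata, taxonomy) -> None:
    """Write the trio back as TSV (counts stored taxa x samples)."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts.T.to_csv(outdir / "counts.tsv", sep="\t", index_label="taxon_id")
    metadata.to_csv(outdir / "metadata.tsv", sep="\t", index_label="sample_id")
    tax = taxonomy[["lineage"]] if "lineage" in taxonomy.columns else taxonomy
    tax.to_csv(outdir / "taxonomy.tsv", sep="\t", index_label="taxon_id")


# ---------------------------------------------------------------------------
# filters


def filter_taxa(
    counts: pd.DataFrame,
    taxonomy: pd.DataFrame,
    min_samples: int = 3,
    excluded_lineages=DEFAULT_EXCLUDED_LINEAGES,
) -> pd.DataFrame:
    """Remove non-bacterial/organellar lineages and rare taxa.

    A taxon is excluded if any rank field of its lineage contains any excluded
    token (case-insensitive substring), or if it has nonzero counts in fewer
    than ``min_samples`` samples (inclusive: present in exactly
    ``min_samples`` is kept).  Samples are never dropped here.
    """
    if min_samples < 1:
        raise InputError("min_samples must be >= 1")
    tokens = [t.lower() for t in excluded_lineages]
    tax = taxonomy.reindex(counts.columns)
    rank_cols = [r for r in RANKS if r in tax.columns]
    lineage_text = tax[rank_cols].fillna("").astype(str).agg(";".join, axis=1)
    lineage_text = lineage_text.str.lower()
    excluded_mask = pd.Series(False, index=counts.columns)
    for tok in tokens:
        excluded_mask |= lineage_text.str.contains(tok, regex=False)
    prevalence = (counts > 0).sum(axis=0)
    keep = counts.columns[(~excluded_mask) & (prevalence >= min_samples)]
    n_removed = counts.shape[1] - len(keep)
    if n_removed:
        logger.info(
            "filter_taxa removed %d of %d taxa (%d excluded lineages)",
            n_removed,
            counts.shape[1],
            int(excluded_mask.sum()),
        )
    if len(keep) == 0:
        logger.warning("filter_taxa removed every taxon")
    return counts.loc[:, keep]


def rarefy(counts: pd.DataFrame, depth: int = 14221, seed=None) -> pd.DataFrame:
    """Subsample every sample to ``depth`` reads without replacement.

    Samples whose total is below ``depth`` are dropped (logged).  The draw is
    multivariate hypergeometric, so a sample whose total equals ``depth`` is
    returned unchanged.  Deterministic given ``seed``.
    """
    if depth < 1:
        raise InputError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = counts.sum(axis=1)
    keep = totals.index[totals >= depth]
    dropped = totals.index.difference(keep)
    if len(dropped):
        logger.warning(
            "rarefy dropped %d samples below depth %d: %s",
            len(dropped),
            depth,
            list(dropped),
        )
    if len(keep) == 0:
        raise InputError(f"all samples below rarefaction depth {depth}")
    out = np.empty((len(keep), counts.shape[1]), dtype=np.int64)
    for i, s in enumerate(keep):
        row = counts.loc[s].to_numpy()
        if row.sum() == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth)
    return pd.DataFrame(out, index=keep, columns=counts.columns)


def to_relative(counts: pd.DataFrame) -> pd.DataFrame:
    """Convert counts to per-sample relative abundances (rows sum to 1)."""
    totals = counts.sum(axis=1)
    zero = totals.index[totals == 0]
    if len(zero):
        raise InputError(f"zero-total sample(s): {list(zero)}")
    return counts.div(totals, axis=0)


UNASSIGNED = "unassigned@{rank}"


def collapse_rank(
    counts: pd.DataFrame, taxonomy: pd.DataFrame, rank: str
) -> pd.DataFrame:
    """Sum counts over taxa sharing the lineage prefix up to ``rank``.

    ``rank`` is one of phylum...genus (or "asv", returning the input
    unchanged).  Taxa unassigned at the rank are pooled into an explicit
    ``unassigned@<rank>`` bin; per-sample totals are conserved exactly.
    """
    rank = rank.lower()
    if rank == "asv":
        return counts.copy()
    if rank not in RANKS[1:6]:
        raise InputError(f"invalid rank {rank!r}; choose phylum..genus or asv")
    upto = RANKS.index(rank) + 1
    tax = taxonomy.reindex(counts.columns)
    unassigned_bin = UNASSIGNED.format(rank=rank)

    def label(taxon):
        fields = [str(tax.loc[taxon, r]) if pd.notna(tax.loc[taxon, r]) else ""
                  for r in RANKS[:upto]]
        if fields[-1] == "" or fields[-1] == "nan":
            return unassigned_bin
        return ";".join(
            f"{RANK_PREFIXES[i]}{fields[i]}" for i in range(upto)
        )

    labels = pd.Index([label(t) for t in counts.columns])
    collapsed = counts.T.groupby(labels, sort=True).sum().T
    return collapsed
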