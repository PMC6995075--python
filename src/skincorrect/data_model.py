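"""Core containers and I/O for amplicon community analysis.

The central object is the :class:`FeatureTable`, an integer count matrix of
samples by ASVs (amplicon sequence variants).  Sample metadata, a ranked
taxonomy and a rooted phylogeny over the ASVs travel alongside it; the
:func:`align` helper restricts all four to a mutually consistent universe
before any analysis stage runs.

File formats are deliberately plain: TSV for tables and metadata, Newick for
the tree, and the minimal dense BIOM-JSON dialect for interoperability with
amplicon toolchains.  Lines starting with ``##`` in any TSV are provenance
comments and are skipped on read.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

SAMPLE_TYPES = frozenset({"swab", "water"})

#: metadata columns carrying water physicochemical measurements
MEASUREMENT_COLUMNS = ("temperature", "conductivity", "ph", "dissolved_oxygen")

_META_COLUMNS = (
    "sample_type",
    "site",
    "stream",
    "basin",
    "fish_taxon",
    "temperature",
    "conductivity",
    "ph",
    "dissolved_oxygen",
    "eutrophic",
)


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


def _check_unique(ids, what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class FeatureTable:
    """Samples x features matrix of non-negative integer read counts.

    Parameters
    ----------
    counts : pandas.DataFrame
        Rows indexed by sample id, columns by feature (ASV) id.  Values must
        be non-negative integers; floats that are exactly integral are cast.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        _check_unique(df.index, "sample")
        _check_unique(df.columns, "feature")
        values = df.to_numpy()
        if values.size:
            if not np.isfinite(values.astype(float)).all():
                raise ValidationError("counts contain non-finite values")
            frac = values.astype(float) % 1
            if (frac != 0).any():
                s, f = np.argwhere(frac != 0)[0]
                raise ValidationError(
                    f"non-integer count at sample {df.index[s]!r}, "
                    f"feature {df.columns[f]!r}"
                )
            if (values < 0).any():
                s, f = np.argwhere(values < 0)[0]
                raise ValidationError(
                    f"negative count at sample {df.index[s]!r}, "
                    f"feature {df.columns[f]!r}"
                )
        self.counts = df.astype(np.int64)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def select_samples(self, sample_ids) -> "FeatureTable":
        return FeatureTable(self.counts.loc[list(sample_ids)].copy())

    def select_features(self, feature_ids) -> "FeatureTable":
        return FeatureTable(self.counts[list(feature_ids)].copy())

    def __eq__(self, other) -> bool:  # count-exact equality
        return isinstance(other, FeatureTable) and self.counts.equals(other.counts)


@dataclass
class TaxonomyTable:
    """Feature id -> semicolon-delimited ranked lineage."""

    lineages: pd.Series  # index: feature id, values: str

    def __post_init__(self) -> None:
        _check_unique(self.lineages.index, "feature")
        self.lineages = self.lineages.astype(str)
        for fid, lin in self.lineages.items():
            if len([t for t in lin.split(";")]) > len(RANKS):
                raise ValidationError(
                    f"lineage for {fid!r} has more than {len(RANKS)} ranks"
                )

    def ranks(self) -> pd.DataFrame:
        """Lineages split into the seven canonical ranks.

        Unassigned ranks become empty strings (explicit placeholders).
        """
        rows = {}
        for fid, lin in self.lineages.items():
            tokens = [t.strip() for t in lin.split(";")]
            tokens += [""] * (len(RANKS) - len(tokens))
            rows[fid] = tokens[: len(RANKS)]
        return pd.DataFrame.from_dict(rows, orient="index", columns=RANKS)

    def rank_label(self, rank: str) -> pd.Series:
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
        return self.ranks()[rank]


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a sample metadata frame.

    The frame is indexed by sample id.  ``sample_type`` must be ``swab`` or
    ``water``; water samples may not carry a fish taxon.  Physicochemical
    columns are floats with NaN for missing; missingness propagates as
    pair-exclusion in downstream correlations.
    """
    meta = meta.copy()
    _check_unique(meta.index, "sample")
    if "sample_type" not in meta.columns:
        raise ValidationError("metadata lacks a sample_type column")
    bad = set(meta["sample_type"]) - SAMPLE_TYPES
    if bad:
        raise ValidationError(f"unknown sample_type token(s): {sorted(bad)}")
    for col in _META_COLUMNS:
        if col not in meta.columns:
            meta[col] = np.nan
    for col in MEASUREMENT_COLUMNS:
        cleaned = meta[col].where(~meta[col].isin(["", "NA"]), np.nan)
        meta[col] = pd.to_numeric(cleaned)
    meta["fish_taxon"] = meta["fish_taxon"].replace({"": np.nan, "NA": np.nan})
    water = meta["sample_type"] == "water"
    offending = meta.index[water & meta["fish_taxon"].notna()]
    if len(offending):
        raise ValidationError(
            f"water sample(s) with fish_taxon set: {list(offending)}"
        )
    if meta["eutrophic"].isna().all():
        meta["eutrophic"] = False
    else:
        truthy = {"True", "true", "1", "1.0", True, 1}
        meta["eutrophic"] = meta["eutrophic"].map(
            lambda v: v in truthy if pd.notna(v) else False).astype(bool)
    return meta[list(_META_COLUMNS)]


# ---------------------------------------------------------------------------
# readers / writers


def _open_skipping_provenance(path):
    with open(path) as fh:
        lines = [ln for ln in fh if not ln.startswith("##")]
    return lines


def read_feature_table(path, format: str = "tsv",
                       orientation: str = "features") -> FeatureTable:
    """Read a feature table from TSV or minimal dense BIOM-JSON.

    The TSV dialect has features as rows and samples as columns with a
    ``#FeatureID`` header cell (``orientation="features"``, the default);
    ``orientation="samples"`` reads the transpose.
    """
    if format == "tsv":
        from io import StringIO

        lines = _open_skipping_provenance(path)
        df = pd.read_csv(StringIO("".join(lines)), sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        if orientation == "features":
            df = df.T  # -> samples x features
        elif orientation != "samples":
            raise ValueError("orientation must be 'features' or 'samples'")
        return FeatureTable(df)
    if format == "biom-json":
        with open(path) as fh:
            doc = json.load(fh)
        feature_ids = [r["id"] for r in doc["rows"]]
        sample_ids = [c["id"] for c in doc["columns"]]
        shape = (len(feature_ids), len(sample_ids))
        data = np.zeros(shape)
        if doc.get("matrix_type") == "sparse":
            for r, c, v in doc["data"]:
                data[int(r), int(c)] = v
        else:
            data = np.asarray(doc["data"], dtype=float).reshape(shape)
        df = pd.DataFrame(data.T, index=sample_ids, columns=feature_ids)
        return FeatureTable(df)
    raise ValueError(f"unknown format {format!r}")


def write_feature_table(table: FeatureTable, path, format: str = "tsv",
                        provenance: str | None = None) -> None:
    if format == "tsv":
        with open(path, "w") as fh:
            if provenance:
                for line in provenance.splitlines():
                    fh.write(f"## {line}\n")
            df = table.counts.T  # features as rows
            fh.write("#FeatureID\t" + "\t".join(map(str, df.columns)) + "\n")
            for fid, row in df.iterrows():
                fh.write(str(fid) + "\t" + "\t".join(str(int(v)) for v in row) + "\n")
        return
    if format == "biom-json":
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "skincorrect",
            "matrix_type": "dense",
            "matrix_element_type": "int",
            "shape": [len(table.feature_ids), len(table.sample_ids)],
            "rows": [{"id": f, "metadata": None} for f in table.feature_ids],
            "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
            "data": table.counts.T.to_numpy().astype(int).tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)
        return
    raise ValueError(f"unknown format {format!r}")


def read_metadata(path) -> pd.DataFrame:
    """Read a sample metadata TSV (empty cells / ``NA`` become missing)."""
    from io import StringIO

    lines = _open_skipping_provenance(path)
    df = pd.read_csv(StringIO("".join(lines)), sep="\t", dtype=str,
                     keep_default_na=False)
    if "sample_id" not in df.columns:
        raise ValidationError("metadata lacks a sample_id column")
    df = df.set_index("sample_id")
    df = df.where(~df.isin(["", "NA"]), np.nan)
    return validate_metadata(df)


def write_metadata(meta: pd.DataFrame, path) -> None:
    out = meta.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", na_rep="NA")


def read_taxonomy(path) -> TaxonomyTable:
    """Two-column TSV: feature id, semicolon-delimited lineage."""
    from io import StringIO

    lines = _open_skipping_provenance(path)
    df = pd.read_csv(StringIO("".join(lines)), sep="\t", dtype=str,
                     keep_default_na=False)
    df = df.set_index(df.columns[0])
    return TaxonomyTable(df[df.columns[0]])


def write_taxonomy(tax: TaxonomyTable, path) -> None:
    out = tax.lineages.rename("lineage").to_frame()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


def read_tree(path) -> TreeNode:
    """Read a rooted Newick tree; missing branch lengths become 0.

    A tree whose root has more than two children is treated as unrooted and
    rejected: Faith PD and the rooted UniFrac definition used here both
    require an explicit root.
    """
    tree = TreeNode.read(str(path), format="newick")
    if len(tree.children) > 2:
        raise ValidationError(
            "tree root has more than two children; supply a rooted tree"
        )
    for node in tree.traverse(include_self=True):
        if node.length is None:
            node.length = 0.0
        if not np.isfinite(node.length) or node.length < 0:
            raise ValidationError(
                f"branch length of node {node.name!r} is not finite/non-negative"
            )
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# alignment


@dataclass
class MismatchReport:
    samples_only_in_table: list = field(default_factory=list)
    samples_only_in_metadata: list = field(default_factory=list)
    features_missing_from_tree: list = field(default_factory=list)
    features_missing_from_taxonomy: list = field(default_factory=list)

    def is_empty(self) -> bool:
        return not (
            self.samples_only_in_table
            or self.samples_only_in_metadata
            or self.features_missing_from_tree
            or self.features_missing_from_taxonomy
        )


@dataclass
class Bundle:
    table: FeatureTable
    metadata: pd.DataFrame
    tree: TreeNode | None
    taxonomy: TaxonomyTable | None
    report: MismatchReport


def align(table: FeatureTable, meta: pd.DataFrame,
          tree: TreeNode | None = None,
          taxonomy: TaxonomyTable | None = None) -> Bundle:
    """Restrict table and metadata to shared samples; report (never silently
    drop) features absent from the tree or taxonomy."""
    shared = [s for s in table.sample_ids if s in meta.index]
    if not shared:
        raise ValidationError("no samples shared between table and metadata")
    report = MismatchReport(
        samples_only_in_table=[s for s in table.sample_ids if s not in meta.index],
        samples_only_in_metadata=[s for s in meta.index if s not in set(table.sample_ids)],
    )
    sub_table = table.select_samples(shared)
    sub_meta = meta.loc[shared]
    if tree is not None:
        tips = {t.name for t in tree.tips()}
        report.features_missing_from_tree = [
            f for f in sub_table.feature_ids if f not in tips
        ]
    if taxonomy is not None:
        known = set(taxonomy.lineages.index)
        report.features_missing_from_taxonomy = [
            f for f in sub_table.feature_ids if f not in known
        ]
    return Bundle(sub_table, sub_meta, tree, taxonomy, report)
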