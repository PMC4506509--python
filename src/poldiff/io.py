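"""Reading, validation and cleaning of spectral-count tables and run designs.

The on-disk dialect is deliberately minimal: long (tidy) tab-separated text
with a header row.  A protein absent from a run is an implicit raw count of
zero — readers never materialize zeros, downstream code treats absence as 0,
mirroring how search engines report only identified proteins.

Counts TSV columns:   ``protein_id  run_id  count``
Design TSV columns:   ``run_id  condition  replicate_index  pair_id``
Condition tokens are exactly ``WT``, ``MUT:<name>`` or ``EV``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DesignError, FormatError, ValidationError

__all__ = [
    "RAW",
    "NORMALIZED",
    "IMPUTED",
    "DEFAULT_CONTAMINANTS",
    "SpectralCountTable",
    "RunDesign",
    "read_spectral_counts",
    "write_spectral_counts",
    "read_run_design",
    "write_run_design",
    "clean_protein_table",
]

RAW = "raw"
IMPUTED = "imputed"
NORMALIZED = "normalized"
_KINDS = (RAW, IMPUTED, NORMALIZED)

COUNT_COLUMNS = ["protein_id", "run_id", "count"]
DESIGN_COLUMNS = ["run_id", "condition", "replicate_index", "pair_id"]

_CONDITION_RE = re.compile(r"^(WT|EV|MUT:[A-Za-z0-9_.\-]+)$")

#: Keratins are the classic affinity-purification contaminants (skin/hair
#: proteins not expressed in HeLa cells); the list is user-overridable.
DEFAULT_CONTAMINANTS = frozenset(
    {
        "KRT1", "KRT2", "KRT5", "KRT6A", "KRT9", "KRT10",
        "KRT14", "KRT16", "KRT17", "KRT77",
    }
)


@dataclass(frozen=True)
class SpectralCountTable:
    """Long-format protein x run spectral counts.

    Parameters
    ----------
    data
        DataFrame with columns ``protein_id``, ``run_id``, ``count``.
    kind
        ``"raw"`` (integer Mascot-style counts), ``"imputed"`` (zeros replaced
        by noise draws, fractional) or ``"normalized"`` (bait-normalized,
        fractional).
    """

    data: pd.DataFrame
    kind: str = RAW

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValidationError(f"unknown table kind {self.kind!r}")
        df = self.data
        missing = [c for c in COUNT_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"count table is missing column(s) {missing}")
        df = df.loc[:, COUNT_COLUMNS].reset_index(drop=True)
        df["protein_id"] = df["protein_id"].astype(str)
        df["run_id"] = df["run_id"].astype(str)
        counts = pd.to_numeric(df["count"], errors="coerce")
        if counts.isna().any():
            bad = df.loc[counts.isna(), "protein_id"].iloc[0]
            raise ValidationError(f"non-numeric count for protein {bad!r}")
        if (counts < 0).any():
            bad = df.loc[counts < 0].iloc[0]
            raise ValidationError(
                f"negative count for ({bad.protein_id}, {bad.run_id})"
            )
        if self.kind == RAW:
            if not np.allclose(counts, np.round(counts), atol=0, rtol=0):
                bad = df.loc[counts != np.round(counts)].iloc[0]
                raise ValidationError(
                    f"non-integer raw count for ({bad.protein_id}, {bad.run_id})"
                )
            df["count"] = counts.astype(np.int64)
        else:
            df["count"] = counts.astype(float)
        dup = df.duplicated(subset=["protein_id", "run_id"])
        if dup.any():
            bad = df.loc[dup].iloc[0]
            raise ValidationError(
                f"duplicate record for ({bad.protein_id}, {bad.run_id})"
            )
        object.__setattr__(self, "data", df)

    # -- convenience accessors -------------------------------------------
    @property
    def proteins(self) -> list[str]:
        return sorted(self.data["protein_id"].unique())

    @property
    def runs(self) -> list[str]:
        return sorted(self.data["run_id"].unique())

    def matrix(self, runs: list[str] | None = None) -> pd.DataFrame:
        """Wide protein x run matrix; absent entries are explicit zeros."""
        mat = self.data.pivot(index="protein_id", columns="run_id", values="count")
        if runs is not None:
            mat = mat.reindex(columns=runs)
        return mat.fillna(0.0).astype(float)

    def with_data(self, data: pd.DataFrame, kind: str | None = None) -> "SpectralCountTable":
        return SpectralCountTable(data=data, kind=self.kind if kind is None else kind)

    def __eq__(self, other: object) -> bool:  # value semantics, used in tests
        if not isinstance(other, SpectralCountTable):
            return NotImplemented
        a = self.data.sort_values(["protein_id", "run_id"]).reset_index(drop=True)
        b = other.data.sort_values(["protein_id", "run_id"]).reset_index(drop=True)
        return self.kind == other.kind and a.equals(b)


@dataclass(frozen=True)
class RunDesign:
    """Condition / replicate / pairing metadata for purification runs.

    Each replicate analysis of a mutant bait is paired with the wild-type
    analysis performed at the same time; pairing is encoded by a shared
    ``pair_id`` between one WT run and (per mutant variant) one MUT run.
    EV (empty-vector background) runs carry an empty ``pair_id``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"run design is missing column(s) {missing}")
        df = df.loc[:, DESIGN_COLUMNS].reset_index(drop=True)
        df["run_id"] = df["run_id"].astype(str)
        df["condition"] = df["condition"].astype(str)
        df["pair_id"] = df["pair_id"].fillna("").astype(str)
        if df["run_id"].duplicated().any():
            raise DesignError("duplicate run_id in design")
        bad = ~df["condition"].str.match(_CONDITION_RE)
        if bad.any():
            raise DesignError(
                f"unknown condition token {df.loc[bad, 'condition'].iloc[0]!r}"
            )
        rep = pd.to_numeric(df["replicate_index"], errors="coerce")
        if rep.isna().any() or (rep < 1).any() or (rep != rep.round()).any():
            raise DesignError("replicate_index must be an integer >= 1")
        df["replicate_index"] = rep.astype(int)
        object.__setattr__(self, "data", df)
        self._check_pairing()

    def _check_pairing(self) -> None:
        df = self.data
        wt = df[df["condition"] == "WT"]
        if wt["pair_id"].eq("").any():
            raise DesignError("WT run without pair_id")
        if wt["pair_id"].duplicated().any():
            raise DesignError("two WT runs share a pair_id")
        wt_pairs = set(wt["pair_id"])
        for variant in self.variants:
            mut = df[df["condition"] == f"MUT:{variant}"]
            if mut["pair_id"].eq("").any():
                run = mut.loc[mut["pair_id"].eq(""), "run_id"].iloc[0]
                raise DesignError(f"MUT run {run!r} has no pair_id")
            if mut["pair_id"].duplicated().any():
                pid = mut.loc[mut["pair_id"].duplicated(), "pair_id"].iloc[0]
                raise DesignError(
                    f"two MUT:{variant} runs paired to the same WT run ({pid!r})"
                )
            dangling = set(mut["pair_id"]) - wt_pairs
            if dangling:
                raise DesignError(
                    f"MUT:{variant} paired to nonexistent WT run ({sorted(dangling)[0]!r})"
                )

    # -- accessors --------------------------------------------------------
    @property
    def variants(self) -> list[str]:
        conds = self.data["condition"]
        return sorted(
            {c.split(":", 1)[1] for c in conds.unique() if c.startswith("MUT:")}
        )

    def runs_for(self, condition: str) -> list[str]:
        """Run ids for a condition token (``WT``, ``EV`` or ``MUT:<name>``),
        ordered by replicate index."""
        sub = self.data[self.data["condition"] == condition]
        return list(sub.sort_values("replicate_index")["run_id"])

    def pairs(self, variant: str) -> list[tuple[str, str]]:
        """(wt_run, mut_run) pairs for a variant, ordered by WT replicate."""
        df = self.data
        wt = df[df["condition"] == "WT"].set_index("pair_id")
        mut = df[df["condition"] == f"MUT:{variant}"]
        if mut.empty:
            raise DesignError(f"no runs for variant {variant!r}")
        out = [
            (wt.loc[row.pair_id, "run_id"], row.run_id)
            for row in mut.sort_values("replicate_index").itertuples()
        ]
        return out


# ---------------------------------------------------------------------------
# File I/O


def _read_tsv(path, columns: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed TSV
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    return df


def read_spectral_counts(path, kind: str = RAW) -> SpectralCountTable:
    """Read a long-format counts TSV into a validated table."""
    df = _read_tsv(path, COUNT_COLUMNS)
    return SpectralCountTable(data=df, kind=kind)


def write_spectral_counts(table: SpectralCountTable, path) -> None:
    """Write the canonical TSV dialect (round-trips exactly through
    :func:`read_spectral_counts`)."""
    df = table.data.copy()
    if table.kind == RAW:
        df["count"] = df["count"].astype(np.int64).map(str)
    else:
        df["count"] = df["count"].map(repr)
    df.to_csv(path, sep="\t", index=False)


def read_run_design(path) -> RunDesign:
    df = _read_tsv(path, DESIGN_COLUMNS)
    return RunDesign(data=df)


def write_run_design(design: RunDesign, path) -> None:
    design.data.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Cleaning


def clean_protein_table(
    table: SpectralCountTable,
    contaminants: frozenset[str] | set[str] | None = None,
    isoform_map: dict[str, str] | None = None,
) -> SpectralCountTable:
    """Drop contaminant proteins, then collapse indistinguishable isoforms.

    Contaminant removal wins over isoform merging: a contaminant mapped into
    an isoform group is removed before the merge.  Isoform groups are summed
    per run (counts are additive evidence for the merged protein).
    """
    if contaminants is None:
        contaminants = DEFAULT_CONTAMINANTS
    df = table.data
    df = df[~df["protein_id"].isin(contaminants)]
    if isoform_map:
        df = df.copy()
        df["protein_id"] = df["protein_id"].map(lambda p: isoform_map.get(p, p))
        df = (
            df.groupby(["protein_id", "run_id"], as_index=False, sort=True)["count"]
            .sum()
        )
    return table.with_data(df.reset_index(drop=True))
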