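"""Typed containers and strict readers/writers for every table the pipeline touches.

All downstream modules consume the in-memory objects defined here; nothing
else in the package parses files.  Identifiers are opaque case-sensitive
strings (tissue labels are the one case-insensitive exception).  Matrices are
pandas DataFrames with the entity id as index and sample/patient ids as
columns.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "ExpressionBundle",
    "PhosphoTable",
    "SERecord",
    "SETable",
    "PathwayCollection",
    "SurvivalTable",
    "KinaseSubstrateMap",
    "parse_site_id",
    "read_expression",
    "write_expression",
    "read_phospho",
    "write_phospho",
    "read_gmt",
    "write_gmt",
    "read_se_table",
    "write_se_table",
    "read_survival",
    "write_survival",
    "read_ks_map",
    "write_ks_map",
    "read_regulons",
    "write_regulons",
]


class FormatError(ValueError):
    """Malformed external input: names the offending row/column/sample."""


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass
class ExpressionBundle:
    """Paired tumor / normal-adjacent-tissue count matrices.

    Column ``j`` of both matrices belongs to the same patient, so a paired
    (matched-sample) statistic can be computed column-wise.
    """

    counts_tumor: pd.DataFrame  # genes x patients, non-negative integers
    counts_nat: pd.DataFrame  # same shape, same index/columns

    def __post_init__(self) -> None:
        t, n = self.counts_tumor, self.counts_nat
        if not t.index.equals(n.index):
            raise FormatError("tumor and NAT gene orderings differ")
        if not t.columns.equals(n.columns):
            raise FormatError("tumor and NAT patient orderings differ")
        if t.index.has_duplicates:
            dup = t.index[t.index.duplicated()][0]
            raise FormatError(f"duplicate gene id: {dup!r}")
        if t.columns.has_duplicates:
            dup = t.columns[t.columns.duplicated()][0]
            raise FormatError(f"duplicate patient id: {dup!r}")
        for name, m in (("tumor", t), ("nat", n)):
            arr = m.to_numpy()
            if not np.issubdtype(arr.dtype, np.number):
                raise FormatError(f"{name} counts are not numeric")
            if np.any(arr < 0):
                raise FormatError(f"{name} counts contain negative values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts_tumor.index)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.counts_tumor.columns)

    @property
    def n_patients(self) -> int:
        return self.counts_tumor.shape[1]


_SITE_RE = re.compile(r"^(?P<protein>.+?)[\-:_](?P<residue>[STY])(?P<pos>\d+)$")


def parse_site_id(raw: str) -> tuple[str, str]:
    """Normalize a phosphosite id to ``PROTEIN_RESIDUEPOS`` form.

    Accepts ``MYH9_S1943``, ``MYH9-S1943`` and ``MYH9:S1943``; the residue
    must be S, T or Y.  Returns ``(site_id, protein_id)``.
    """
    m = _SITE_RE.match(raw.strip())
    if m is None:
        raise FormatError(f"unparseable phosphosite id: {raw!r}")
    protein = m.group("protein")
    site = f"{protein}_{m.group('residue')}{m.group('pos')}"
    return site, protein


@dataclass
class PhosphoTable:
    """Phosphosite x patient log2 fold-change matrix (tumor vs NAT).

    ``complete_sites`` flags sites quantified in every patient; it is always
    derived from missingness, never supplied by the caller.
    """

    log2fc: pd.DataFrame  # sites x patients, float, NaN = not detected
    protein_of_site: dict[str, str]
    complete_sites: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        if self.log2fc.index.has_duplicates:
            dup = self.log2fc.index[self.log2fc.index.duplicated()][0]
            raise FormatError(f"duplicate site id: {dup!r}")
        missing = [s for s in self.log2fc.index if s not in self.protein_of_site]
        if missing:
            raise FormatError(f"site without protein annotation: {missing[0]!r}")
        arr = self.log2fc.to_numpy(dtype=float)
        if np.any(np.isinf(arr)):
            raise FormatError("log2fc contains infinite values")
        self.complete_sites = pd.Series(
            ~np.isnan(arr).any(axis=1), index=self.log2fc.index
        )

    @property
    def site_ids(self) -> list[str]:
        return list(self.log2fc.index)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.log2fc.columns)


@dataclass(frozen=True)
class SERecord:
    se_id: str
    tissue: str
    tf_ids: frozenset[str]
    gene_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.tf_ids:
            raise FormatError(f"SE record {self.se_id!r} has no bound TFs")
        if not self.gene_ids:
            raise FormatError(f"SE record {self.se_id!r} has no regulated genes")


@dataclass
class SETable:
    """Super-enhancer records: which TFs bind each SE and which genes it regulates."""

    records: list[SERecord]

    def __post_init__(self) -> None:
        ids = [r.se_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise FormatError(f"duplicate se_id: {dup!r}")

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class PathwayCollection:
    """Named gene/protein sets with GMT semantics (member order irrelevant)."""

    pathways: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for name, members in self.pathways.items():
            if not members:
                raise FormatError(f"pathway {name!r} is empty")

    def pathways_of(self, entity: str) -> set[str]:
        return {n for n, m in self.pathways.items() if entity in m}

    def __len__(self) -> int:
        return len(self.pathways)


@dataclass
class SurvivalTable:
    """Per-patient follow-up time and event indicator (1 = death observed)."""

    data: pd.DataFrame  # index patient_id, columns time, event

    def __post_init__(self) -> None:
        d = self.data
        if d.index.has_duplicates:
            dup = d.index[d.index.duplicated()][0]
            raise FormatError(f"duplicate patient id in survival table: {dup!r}")
        if not {"time", "event"} <= set(d.columns):
            raise FormatError("survival table needs columns time,event")
        d.index.name = "patient_id"
        if np.any(d["time"].to_numpy() <= 0):
            bad = d.index[d["time"] <= 0][0]
            raise FormatError(f"non-positive survival time for patient {bad!r}")
        if not set(np.unique(d["event"])) <= {0, 1}:
            raise FormatError("event must be 0 or 1")

    @property
    def patient_ids(self) -> list[str]:
        return list(self.data.index)


@dataclass
class KinaseSubstrateMap:
    """Kinase -> set of phosphosite ids (same id dialect as PhosphoTable)."""

    substrates: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for k, sites in self.substrates.items():
            if not sites:
                raise FormatError(f"kinase {k!r} has an empty substrate set")

    def __len__(self) -> int:
        return len(self.substrates)


# --------------------------------------------------------------------------
# Matrix TSV helpers
# --------------------------------------------------------------------------


def _read_matrix_tsv(path, value_dtype: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate row id {dup!r}")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad][0]
            raise FormatError(
                f"{path}: non-numeric cell at row {row!r}, column {col!r}"
            )
        df[col] = vals
    if value_dtype == "int":
        arr = df.to_numpy()
        if np.isnan(arr).any():
            row = df.index[np.isnan(arr).any(axis=1)][0]
            raise FormatError(f"{path}: missing count at row {row!r}")
        if not np.allclose(arr, np.round(arr)):
            raise FormatError(f"{path}: counts must be integers")
        df = df.round().astype(np.int64)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def _write_matrix_tsv(df: pd.DataFrame, path, id_label: str) -> None:
    df.to_csv(path, sep="\t", index_label=id_label, float_format="%.10g")


# --------------------------------------------------------------------------
# Expression
# --------------------------------------------------------------------------


def read_expression(tumor_path, nat_path, pairing_path) -> ExpressionBundle:
    """Read paired tumor/NAT count TSVs plus a sample-pairing table.

    The pairing file is TSV with header ``patient_id  tumor_sample  nat_sample``;
    matrices are column-reordered to its patient order.  Genes present in only
    one matrix are dropped with a warning; unpairable samples are hard errors.
    """
    tumor = _read_matrix_tsv(tumor_path, "int")
    nat = _read_matrix_tsv(nat_path, "int")
    pairing = pd.read_csv(pairing_path, sep="\t", dtype=str)
    need = {"patient_id", "tumor_sample", "nat_sample"}
    if not need <= set(pairing.columns):
        raise FormatError(f"{pairing_path}: pairing file needs columns {sorted(need)}")

    for col, df, label in (
        ("tumor_sample", tumor, "tumor"),
        ("nat_sample", nat, "nat"),
    ):
        missing = [s for s in pairing[col] if s not in df.columns]
        if missing:
            raise FormatError(f"pairing names absent {label} sample {missing[0]!r}")
        extra = sorted(set(df.columns) - set(pairing[col]))
        if extra:
            raise FormatError(
                f"unpairable {label} sample(s) not in pairing file: {', '.join(extra)}"
            )

    common = tumor.index.intersection(nat.index)
    dropped = len(tumor.index.symmetric_difference(nat.index))
    if dropped:
        logger.warning("dropping %d genes present in only one matrix", dropped)
        warnings.warn(f"{dropped} genes present in only one expression file dropped")
    tumor = tumor.loc[common, list(pairing["tumor_sample"])]
    nat = nat.loc[common, list(pairing["nat_sample"])]
    tumor.columns = list(pairing["patient_id"])
    nat.columns = list(pairing["patient_id"])
    return ExpressionBundle(counts_tumor=tumor, counts_nat=nat)


def write_expression(bundle: ExpressionBundle, tumor_path, nat_path, pairing_path) -> None:
    """Write a bundle back to the three-file on-disk dialect read_expression expects."""
    patients = bundle.patient_ids
    tumor = bundle.counts_tumor.copy()
    nat = bundle.counts_nat.copy()
    tumor.columns = [f"{p}-T" for p in patients]
    nat.columns = [f"{p}-N" for p in patients]
    _write_matrix_tsv(tumor, tumor_path, "gene_id")
    _write_matrix_tsv(nat, nat_path, "gene_id")
    pd.DataFrame(
        {
            "patient_id": patients,
            "tumor_sample": [f"{p}-T" for p in patients],
            "nat_sample": [f"{p}-N" for p in patients],
        }
    ).to_csv(pairing_path, sep="\t", index=False)


# --------------------------------------------------------------------------
# Phospho
# --------------------------------------------------------------------------


def read_phospho(path) -> PhosphoTable:
    """Read a site x patient log2FC TSV; empty cells mean not detected."""
    df = _read_matrix_tsv(path, "float")
    sites, proteins = {}, {}
    for raw in df.index:
        site, protein = parse_site_id(raw)
        if site in proteins:
            raise FormatError(f"{path}: duplicate site id {site!r}")
        sites[raw] = site
        proteins[site] = protein
    df.index = [sites[r] for r in df.index]
    return PhosphoTable(log2fc=df.astype(float), protein_of_site=proteins)


def write_phospho(table: PhosphoTable, path) -> None:
    _write_matrix_tsv(table.log2fc, path, "site_id")


# --------------------------------------------------------------------------
# GMT
# --------------------------------------------------------------------------


def read_gmt(path) -> PathwayCollection:
    """Read standard GMT: name, description, members, tab-separated."""
    pathways: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has <3 fields")
            name = fields[0]
            if name in pathways:
                raise FormatError(f"{path}:{lineno}: duplicate pathway name {name!r}")
            members = frozenset(f for f in fields[2:] if f)
            if not members:
                raise FormatError(f"{path}:{lineno}: pathway {name!r} has no members")
            pathways[name] = members
    return PathwayCollection(pathways=pathways)


def write_gmt(collection: PathwayCollection, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.pathways):
            members = "\t".join(sorted(collection.pathways[name]))
            fh.write(f"{name}\tna\t{members}\n")


# --------------------------------------------------------------------------
# Super-enhancer table
# --------------------------------------------------------------------------


def read_se_table(path, tissue: str) -> SETable:
    """Read the SE TSV keeping only rows whose tissue matches (case-insensitive)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"se_id", "tissue", "tf_ids", "gene_ids"}
    if not need <= set(df.columns):
        raise FormatError(f"{path}: SE table needs columns {sorted(need)}")
    records = []
    want = tissue.lower()
    for _, row in df.iterrows():
        if str(row["tissue"]).lower() != want:
            continue
        records.append(
            SERecord(
                se_id=row["se_id"],
                tissue=row["tissue"],
                tf_ids=frozenset(t for t in str(row["tf_ids"]).split(";") if t),
                gene_ids=frozenset(g for g in str(row["gene_ids"]).split(";") if g),
            )
        )
    if not records:
        warnings.warn(f"no SE records for tissue {tissue!r}")
    return SETable(records=records)


def write_se_table(table: SETable, path) -> None:
    rows = [
        {
            "se_id": r.se_id,
            "tissue": r.tissue,
            "tf_ids": ";".join(sorted(r.tf_ids)),
            "gene_ids": ";".join(sorted(r.gene_ids)),
        }
        for r in table.records
    ]
    pd.DataFrame(rows, columns=["se_id", "tissue", "tf_ids", "gene_ids"]).to_csv(
        path, sep="\t", index=False
    )


# --------------------------------------------------------------------------
# Survival
# --------------------------------------------------------------------------


def read_survival(path) -> SurvivalTable:
    """Read a CSV with header patient_id,time,event."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    need = {"patient_id", "time", "event"}
    if not need <= set(df.columns):
        raise FormatError(f"{path}: survival table needs columns {sorted(need)}")
    df = df.set_index("patient_id")
    return SurvivalTable(data=df[["time", "event"]].astype({"time": float, "event": int}))


def write_survival(table: SurvivalTable, path) -> None:
    table.data.to_csv(path, index_label="patient_id", float_format="%.10g")


# --------------------------------------------------------------------------
# Kinase-substrate map
# --------------------------------------------------------------------------


def read_ks_map(path) -> KinaseSubstrateMap:
    """Read a TSV with header kinase,site (one edge per line)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"kinase", "site"} <= set(df.columns):
        raise FormatError(f"{path}: kinase-substrate map needs columns kinase,site")
    substrates: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        site, _ = parse_site_id(row["site"])
        substrates.setdefault(row["kinase"], set()).add(site)
    return KinaseSubstrateMap(substrates={k: frozenset(v) for k, v in substrates.items()})


def write_ks_map(ksmap: KinaseSubstrateMap, path) -> None:
    rows = [
        {"kinase": k, "site": s}
        for k in sorted(ksmap.substrates)
        for s in sorted(ksmap.substrates[k])
    ]
    pd.DataFrame(rows, columns=["kinase", "site"]).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# Regulon TSV (shared by regulon_inference / direct_targets outputs)
# --------------------------------------------------------------------------


def write_regulons(regulons: dict, path) -> None:
    """Write regulons as TSV with columns tf, target, mode, r, p, support."""
    rows = []
    for tf in sorted(regulons):
        reg = regulons[tf]
        for target in sorted(reg.targets):
            e = reg.targets[target]
            rows.append(
                {
                    "tf": tf,
                    "target": target,
                    "mode": e.mode,
                    "r": f"{e.r:.10g}",
                    "p": f"{e.p:.10g}",
                    "support": f"{e.support:.10g}",
                }
            )
    pd.DataFrame(rows, columns=["tf", "target", "mode", "r", "p", "support"]).to_csv(
        path, sep="\t", index=False
    )


def read_regulons(path) -> dict:
    from .regulon_inference import Regulon, RegulonEdge

    df = pd.read_csv(path, sep="\t", dtype={"tf": str, "target": str})
    regulons: dict[str, Regulon] = {}
    for _, row in df.iterrows():
        tf = row["tf"]
        reg = regulons.setdefault(tf, Regulon(tf=tf, targets={}))
        reg.targets[row["target"]] = RegulonEdge(
            mode=int(row["mode"]),
            r=float(row["r"]),
            p=float(row["p"]),
            support=float(row["support"]),
        )
    return regulons
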