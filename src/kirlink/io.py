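"""Readers and writers for the toolkit's plain-text table formats.

Two formats tie the pipeline together: a droplet-count CSV (one duplex well
per row, quadrant counts plus sample/assay metadata, in the style of a
vendor export) and a PED-like tab-separated pedigree table carrying
per-gene integer copy numbers and presence/absence columns. Both are UTF-8
with explicit headers; lines starting with '#' are metadata comments that
readers skip.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, fields as dc_fields

import pandas as pd

from .errors import DropletTableError, PedigreeTableError
from .pedigree import FamilyGenotypes
from .quant import QuadrantCounts

#: Accepted aliases (lower-cased) for droplet-table columns, covering common
#: vendor export headers.
_COLUMN_ALIASES = {
    "well": "well",
    "sample": "sample_id",
    "sample_id": "sample_id",
    "samplename": "sample_id",
    "assay": "assay",
    "experiment": "assay",
    "channel_a_target": "channel_a_target",
    "target1": "channel_a_target",
    "ch1_target": "channel_a_target",
    "channel_b_target": "channel_b_target",
    "target2": "channel_b_target",
    "ch2_target": "channel_b_target",
    "n_total": "n_total",
    "accepteddroplets": "n_total",
    "total": "n_total",
    "n_pp": "n_pp",
    "ch1+ch2+": "n_pp",
    "n_pn": "n_pn",
    "ch1+ch2-": "n_pn",
    "n_np": "n_np",
    "ch1-ch2+": "n_np",
    "n_nn": "n_nn",
    "ch1-ch2-": "n_nn",
    "digested": "digested",
}

_REQUIRED = ("well", "sample_id", "assay", "channel_a_target", "channel_b_target",
             "n_total", "n_pp", "n_pn", "n_np", "n_nn")

_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f", ""}


@dataclass(frozen=True)
class DropletCountRecord:
    """One duplex well of a droplet-count table."""

    well: str
    sample_id: str
    assay: str
    channel_a_target: str
    channel_b_target: str
    n_total: int
    n_pp: int
    n_pn: int
    n_np: int
    n_nn: int
    digested: bool = False

    def quadrants(self) -> QuadrantCounts:
        return QuadrantCounts(
            n_nn=self.n_nn, n_pn=self.n_pn, n_np=self.n_np, n_pp=self.n_pp,
            channel_a_name=self.channel_a_target,
            channel_b_name=self.channel_b_target,
        )

    @classmethod
    def from_quadrants(cls, q: QuadrantCounts, well: str, sample_id: str,
                       assay: str, digested: bool = False) -> "DropletCountRecord":
        return cls(
            well=well, sample_id=sample_id, assay=assay,
            channel_a_target=q.channel_a_name, channel_b_target=q.channel_b_name,
            n_total=q.n_total, n_pp=q.n_pp, n_pn=q.n_pn, n_np=q.n_np, n_nn=q.n_nn,
            digested=digested,
        )


def _parse_bool(raw, line_no: int, errors: list) -> bool:
    s = str(raw).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE or s == "nan":
        return False
    errors.append(f"line {line_no}: cannot parse boolean {raw!r}")
    return False


def read_droplet_table(path) -> list:
    """Read and validate a droplet-count CSV.

    Column names are matched case-insensitively against a vendor-alias map.
    All malformed rows are collected and reported together, with line
    numbers, in a single :class:`DropletTableError`.
    """
    df = pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=True)
    rename = {}
    for col in df.columns:
        key = col.strip().lower().replace(" ", "")
        if key in _COLUMN_ALIASES:
            rename[col] = _COLUMN_ALIASES[key]
    df = df.rename(columns=rename)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise DropletTableError([f"missing required column(s): {', '.join(missing)}"])
    errors: list = []
    records = []
    # +2: one for the header line, one for 1-based numbering
    for i, row in df.iterrows():
        line_no = i + 2
        try:
            counts = {c: int(row[c]) for c in ("n_total", "n_pp", "n_pn", "n_np", "n_nn")}
        except (TypeError, ValueError):
            errors.append(f"line {line_no}: non-integer droplet counts")
            continue
        if any(v < 0 for v in counts.values()):
            errors.append(f"line {line_no}: negative droplet count")
            continue
        s = counts["n_pp"] + counts["n_pn"] + counts["n_np"] + counts["n_nn"]
        if s != counts["n_total"]:
            errors.append(
                f"line {line_no}: quadrant counts sum to {s}, n_total is {counts['n_total']}"
            )
            continue
        if counts["n_total"] == 0:
            errors.append(f"line {line_no}: empty well")
            continue
        meta = {c: str(row[c]).strip() for c in
                ("well", "sample_id", "assay", "channel_a_target", "channel_b_target")}
        if any(not v or v == "nan" for v in meta.values()):
            errors.append(f"line {line_no}: empty well/sample/assay/target field")
            continue
        digested = _parse_bool(row["digested"], line_no, errors) if "digested" in df.columns else False
        records.append(DropletCountRecord(**meta, **counts, digested=digested))
    if errors:
        raise DropletTableError(errors)
    return records


def write_droplet_table(records, path, metadata: dict | None = None) -> None:
    """Write droplet-count records as CSV, with an optional '#' metadata
    preamble (seed, parameters) sufficient to reproduce the file."""
    cols = [f.name for f in dc_fields(DropletCountRecord)]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}={val}\n")
        writer = csv.writer(fh)
        writer.writerow(cols)
        for r in records:
            writer.writerow([str(getattr(r, c)).lower() if c == "digested"
                             else getattr(r, c) for c in cols])


# ---------------------------------------------------------------------------
# Pedigree tables

_PED_COLS = ("family", "individual", "father", "mother", "sex")
_MISSING = {"", "na", "nan", "-", ".", "none", "unknown"}


def _parse_cn(raw):
    s = str(raw).strip().lower()
    if s in _MISSING:
        return None
    return int(s)


def read_pedigree_table(path, gene: str = "KIR2DL5") -> list:
    """Read a PED-like TSV into per-family genotype sets.

    Expected columns: family, individual, father, mother, sex, then
    ``<gene>_cn`` integer columns and optional ``KIR2DS3_present`` /
    ``KIR2DS5_present`` boolean columns. '0' in father/mother marks a
    founder. Unknown copy numbers may be left as 'NA'.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in _PED_COLS if c not in df.columns]
    if missing:
        raise PedigreeTableError(f"missing pedigree column(s): {', '.join(missing)}")
    cn_col = f"{gene.lower()}_cn"
    if cn_col not in df.columns:
        raise PedigreeTableError(f"missing copy-number column {cn_col!r}")
    ids = df["individual"].tolist()
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise PedigreeTableError(f"duplicated individual id(s): {sorted(dupes)}")
    known = set(ids)
    families = []
    for fam_id, sub in df.groupby("family", sort=True):
        parents_of_children = set()
        children_rows = []
        for _, row in sub.iterrows():
            fa, mo = row["father"].strip(), row["mother"].strip()
            if (fa == "0") != (mo == "0"):
                raise PedigreeTableError(
                    f"individual {row['individual']}: one parent founder, one not"
                )
            if fa != "0":
                for p in (fa, mo):
                    if p not in known:
                        raise PedigreeTableError(
                            f"individual {row['individual']} references absent parent {p!r}"
                        )
                parents_of_children.add((mo, fa))
                children_rows.append(row)
        if len(parents_of_children) != 1:
            raise PedigreeTableError(
                f"family {fam_id}: expected one nuclear mother/father pair, "
                f"found {len(parents_of_children)}"
            )
        if not children_rows:
            raise PedigreeTableError(f"family {fam_id}: no children")
        mother_id, father_id = next(iter(parents_of_children))
        by_id = {row["individual"]: row for _, row in sub.iterrows()}
        if mother_id not in by_id or father_id not in by_id:
            raise PedigreeTableError(f"family {fam_id}: parents not in the same family block")
        presence = {}
        for _, row in sub.iterrows():
            p3 = row.get("kir2ds3_present")
            p5 = row.get("kir2ds5_present")
            if p3 is not None and p5 is not None and str(p3).lower() not in _MISSING:
                presence[row["individual"]] = (
                    str(p3).strip().lower() in _TRUE,
                    str(p5).strip().lower() in _TRUE,
                )
        families.append(FamilyGenotypes(
            family_id=str(fam_id),
            mother_cn=_parse_cn(by_id[mother_id][cn_col]),
            father_cn=_parse_cn(by_id[father_id][cn_col]),
            children_cn=[_parse_cn(r[cn_col]) for r in children_rows],
            children_ids=[r["individual"] for r in children_rows],
            presence=presence or None,
        ))
    return families


def write_pedigree_table(families, path, gene: str = "KIR2DL5") -> None:
    """Write families back to the PED-like TSV (inverse of the reader for
    simulator-produced families)."""
    cn_col = f"{gene}_cn"
    rows = []
    for fam in families:
        fid = fam.family_id
        mother_id, father_id = f"{fid}-M", f"{fid}-F"
        ids = fam.children_ids or [f"{fid}-C{i}" for i in range(len(fam.children_cn))]

        def prez(label):
            if fam.presence and label in fam.presence:
                a, b = fam.presence[label]
                return str(a).lower(), str(b).lower()
            return "na", "na"

        rows.append((fid, mother_id, "0", "0", "2", fam.mother_cn, *prez("mother")))
        rows.append((fid, father_id, "0", "0", "1", fam.father_cn, *prez("father")))
        for cid, cn in zip(ids, fam.children_cn):
            rows.append((fid, cid, father_id, mother_id, "1", cn, *prez(cid)))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("family\tindividual\tfather\tmother\tsex\t"
                 f"{cn_col}\tKIR2DS3_present\tKIR2DS5_present\n")
        for r in rows:
            fh.write("\t".join("NA" if v is None else str(v) for v in r) + "\n")
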