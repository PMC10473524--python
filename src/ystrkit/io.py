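"""Reading, writing and curating Y-STR haplotype tables.

Supported formats: rectangular CSV/TSV (header ``SampleID, Population,
<locus columns>``; DYS385 as one paired column ``"13,17"`` or as two columns
``DYS385a``/``DYS385b``) and Arlequin ``.arp`` haplotypic projects grouped by
population.

Curation operations implement the standard conventions for population Y-STR
data: DYS389II.I difference recoding, removal of haplotypes carrying
duplicated alleles at single-copy loci, and kit-subset views (e.g. the
17-marker Yfiler-compatible view of a PowerPlex Y23 table).
"""

from __future__ import annotations

import logging
import re
from dataclasses import replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from ystrkit.datamodel import (
    MISSING_TOKENS,
    FilterReport,
    HaplotypeTable,
    validate_allele,
)
from ystrkit.panels import KitPanel

logger = logging.getLogger(__name__)

_ID_COLUMNS = {"SAMPLEID", "SAMPLE", "ID", "SAMPLE_ID"}
_POP_COLUMNS = {"POPULATION", "POP"}


def _norm(name: str) -> str:
    return re.sub(r"[\s\-_]", "", name).upper()


def _resolve_locus(column: str, panel: KitPanel) -> tuple[str, str] | None:
    """Map a header name to ``(locus, role)``.

    role: ``"single"`` (one value per cell), ``"pair"`` (both copies in one
    cell), ``"copy_a"`` / ``"copy_b"`` (split multi-copy columns),
    ``"recoded"`` (a DYS389II.I column standing for recoded DYS389II).
    Returns None when the column is not resolvable.
    """
    norm = _norm(column)
    if norm in {"DYS389II.I", "DYS389III"} or _norm(column).replace(".", "") == "DYS389III":
        return ("DYS389II", "recoded") if "DYS389II" in panel.loci else None
    by_norm = {_norm(l): l for l in panel.loci}
    if norm in by_norm:
        locus = by_norm[norm]
        return locus, ("pair" if locus in panel.multi_copy else "single")
    for locus in panel.multi_copy:
        ln = _norm(locus)
        if norm in {ln + "AB", ln + "A/B"}:
            return locus, "pair"
        if norm == ln + "A":
            return locus, "copy_a"
        if norm == ln + "B":
            return locus, "copy_b"
    return None


def _parse_cell(raw: object, locus: str, row_label: str, multi_copy: bool):
    """Parse one allele cell to float / None / tuple."""
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return None
    text = str(raw).strip()
    if text.lower() in MISSING_TOKENS:
        return None
    parts = [p.strip() for p in re.split(r"[,;/]", text) if p.strip()]
    try:
        values = [validate_allele(float(p)) for p in parts]
    except ValueError as exc:
        raise ValueError(f"row {row_label!r}, locus {locus}: {exc}") from None
    if not values:
        return None
    if len(values) == 1 and not multi_copy:
        return values[0]
    if multi_copy and len(values) != 2:
        raise ValueError(
            f"row {row_label!r}, locus {locus}: multi-copy locus needs exactly 2 alleles, got {len(values)}"
        )
    return tuple(sorted(values))


def infer_panel(columns: Iterable[str], metadata_cols: Sequence[str] = ()) -> KitPanel:
    """Build an ad-hoc :class:`KitPanel` from a table header.

    Every column that is not the sample-ID, population or a named metadata
    column becomes a locus.  ``DYS385`` (paired or split ``a``/``b``
    columns) is the only locus treated as multi-copy; a ``DYS389II.I``
    column is read as recoded DYS389II.
    """
    meta_norm = {_norm(c) for c in metadata_cols}
    loci: list[str] = []
    saw_id = saw_pop = False
    for col in columns:
        norm = _norm(col)
        if norm in _ID_COLUMNS and not saw_id:
            saw_id = True
            continue
        if norm in _POP_COLUMNS and not saw_pop:
            saw_pop = True
            continue
        if norm in meta_norm:
            continue
        if norm.replace(".", "") == "DYS389III":
            locus = "DYS389II"
        elif norm.startswith("DYS385"):
            locus = "DYS385"
        else:
            locus = col.strip()
        if locus not in loci:
            loci.append(locus)
    if not loci:
        raise ValueError("no locus columns found to infer a panel from")
    multi = frozenset({"DYS385"} if "DYS385" in loci else ())
    return KitPanel(name="inferred", loci=tuple(loci), multi_copy=multi)


def read_haplotype_table(
    path: str | Path,
    panel: KitPanel | None = None,
    dialect: str = "auto",
    metadata_cols: Sequence[str] = (),
) -> HaplotypeTable:
    """Read a rectangular haplotype table (CSV or TSV).

    ``"99"``, blank and ``"NA"`` cells become missing; a comma-separated
    pair in a single-copy column is preserved as a duplication record for
    :func:`filter_duplicated_alleles`; ``DYS385`` is accepted either as one
    paired column or as split ``DYS385a``/``DYS385b`` columns.  A column
    named ``DYS389II.I`` is loaded as already-recoded DYS389II and the
    panel's recoding flag is set.

    When ``panel`` is None the panel is inferred from the header via
    :func:`infer_panel`.  ``metadata_cols`` names extra per-sample columns
    (e.g. ``Haplogroup``) to retain; any other unresolvable column is an
    error.
    """
    path = Path(path)
    if dialect == "auto":
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if header.count("\t") > header.count(",") else ","
    else:
        sep = {"csv": ",", "tsv": "\t"}[dialect]
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if panel is None:
        panel = infer_panel(df.columns, metadata_cols)

    meta_norm = {_norm(c) for c in metadata_cols}
    id_col = pop_col = None
    locus_cols: dict[str, tuple[str, str]] = {}
    meta_found: list[str] = []
    recoded = False
    for col in df.columns:
        norm = _norm(col)
        if norm in _ID_COLUMNS and id_col is None:
            id_col = col
            continue
        if norm in _POP_COLUMNS and pop_col is None:
            pop_col = col
            continue
        if norm in meta_norm:
            meta_found.append(col)
            continue
        resolved = _resolve_locus(col, panel)
        if resolved is None:
            raise ValueError(f"unknown locus column {col!r} for panel {panel.name!r}")
        locus_cols[col] = resolved
        if resolved[1] == "recoded":
            recoded = True
    if id_col is None or pop_col is None:
        raise ValueError("table must have SampleID and Population columns")

    covered = {loc for loc, _ in locus_cols.values()}
    missing_loci = set(panel.loci) - covered
    if missing_loci:
        raise ValueError(f"panel loci absent from table: {sorted(missing_loci)}")

    sample_ids = df[id_col].astype(str).tolist()
    populations = df[pop_col].astype(str).tolist()

    data: dict[str, list] = {locus: [None] * len(df) for locus in panel.loci}
    halves: dict[str, dict[str, list]] = {}
    for col, (locus, role) in locus_cols.items():
        cells = [
            _parse_cell(df[col].iat[i], locus, sample_ids[i], role == "pair")
            for i in range(len(df))
        ]
        if role in {"single", "pair", "recoded"}:
            data[locus] = cells
        else:
            halves.setdefault(locus, {})[role] = cells
    for locus, parts in halves.items():
        if set(parts) != {"copy_a", "copy_b"}:
            raise ValueError(f"locus {locus}: need both split columns (a and b)")
        pairs = []
        for a, b in zip(parts["copy_a"], parts["copy_b"]):
            pairs.append(None if a is None or b is None else tuple(sorted((a, b))))
        data[locus] = pairs

    alleles = pd.DataFrame(data, columns=list(panel.loci), dtype=object)
    meta = df[meta_found].copy() if meta_found else None
    out_panel = replace(panel, dys389_recoded=True) if recoded else panel
    return HaplotypeTable(sample_ids, populations, alleles, out_panel, meta)


def recode_dys389(table: HaplotypeTable) -> HaplotypeTable:
    """Replace DYS389II by the DYS389II.I difference encoding.

    DYS389II is typed as the combined repeat number of both DYS389 repeat
    stretches; subtracting DYS389I isolates the second stretch so the locus
    mutates in single steps like every other marker.  Rejected when the
    table is already recoded (guarded by a panel flag).
    """
    if table.panel.dys389_recoded:
        raise ValueError("table is already DYS389II.I-recoded")
    for locus in ("DYS389I", "DYS389II"):
        if locus not in table.panel.loci:
            raise ValueError(f"panel {table.panel.name!r} lacks {locus}")
    out = table.copy()
    for i in range(len(out)):
        a = out.alleles.at[i, "DYS389I"]
        b = out.alleles.at[i, "DYS389II"]
        if isinstance(a, tuple) or isinstance(b, tuple):
            continue  # duplication record; row is destined for the duplicate filter
        if a is None or b is None:
            out.alleles.at[i, "DYS389II"] = None
            continue
        if b < a:
            raise ValueError(
                f"row {out.sample_ids[i]!r}: DYS389II ({b}) < DYS389I ({a}) is an impossible encoding"
            )
        out.alleles.at[i, "DYS389II"] = validate_allele(b - a)
    return HaplotypeTable(
        out.sample_ids,
        out.populations,
        out.alleles,
        replace(out.panel, dys389_recoded=True),
        out.metadata,
    )


def filter_duplicated_alleles(table: HaplotypeTable) -> tuple[HaplotypeTable, FilterReport]:
    """Remove haplotypes with duplicated alleles at any single-copy locus.

    Duplications (two peaks at a normally single-copy Y marker) indicate
    regional duplication of the chromosome and make the haplotype unusable
    for frequency-based forensic statistics.  Multi-copy loci (DYS385a/b)
    never trigger removal.  Retained rows are untouched.
    """
    removed = [i for i in range(len(table)) if table.has_duplication(i)]
    kept = [i for i in range(len(table)) if i not in set(removed)]
    report = FilterReport(
        n_input=len(table),
        n_removed_duplicated=len(removed),
        n_retained=len(kept),
        removed_ids=tuple(table.sample_ids[i] for i in removed),
    )
    if not kept:
        logger.warning("duplicated-allele filter removed every row")
    return table.take(kept), report


def subset_kit(table: HaplotypeTable, subset: Iterable[str]) -> HaplotypeTable:
    """Restrict the table to a locus subset (e.g. the Yfiler17 view)."""
    subset = tuple(subset)
    panel = table.panel.subset(subset)
    return HaplotypeTable(
        table.sample_ids,
        table.populations,
        table.alleles[list(panel.loci)].copy(),
        panel,
        table.metadata,
    )


# ---------------------------------------------------------------------------
# writers


def _format_allele(value, recoded_dys385_sep: str = ",") -> str:
    if value is None:
        return ""
    if isinstance(value, tuple):
        return recoded_dys385_sep.join(_format_allele(v) for v in value)
    if value == int(value):
        return str(int(value))
    return f"{value:.1f}"


def export_table(table: HaplotypeTable, path: str | Path, format: str = "csv") -> Path:
    """Write the table as CSV (lossless round trip) or an Arlequin ``.arp``
    haplotypic project grouped by population."""
    if len(table) == 0:
        raise ValueError("refusing to export an empty table")
    path = Path(path)
    if format == "csv":
        cols: dict[str, list] = {
            "SampleID": table.sample_ids,
            "Population": table.populations,
        }
        for locus in table.panel.loci:
            header = (
                "DYS389II.I"
                if locus == "DYS389II" and table.panel.dys389_recoded
                else locus
            )
            cols[header] = [_format_allele(v) for v in table.alleles[locus]]
        for mcol in table.metadata.columns:
            cols[str(mcol)] = table.metadata[mcol].tolist()
        pd.DataFrame(cols).to_csv(path, index=False)
        return path
    if format == "arlequin":
        _write_arlequin(table, path)
        return path
    raise ValueError(f"unsupported export format {format!r}")


def _marker_columns(panel: KitPanel) -> list[tuple[str, int]]:
    """Flatten loci to per-copy columns: (locus, copy_index)."""
    cols = []
    for locus in panel.loci:
        if locus in panel.multi_copy:
            cols.extend([(locus, 0), (locus, 1)])
        else:
            cols.append((locus, -1))
    return cols


def _write_arlequin(table: HaplotypeTable, path: Path) -> None:
    pops = table.by_population()
    cols = _marker_columns(table.panel)
    lines = [
        "[Profile]",
        f'Title="{table.panel.name} haplotypes"',
        f"NbSamples={len(pops)}",
        "DataType=MICROSAT",
        "GenotypicData=0",
        "GameticPhase=0",
        "MissingData='?'",
        "LocusSeparator=WHITESPACE",
        "",
        "[Data]",
        "[[Samples]]",
    ]
    for pop, sub in pops.items():
        lines.append(f'SampleName="{pop}"')
        lines.append(f"SampleSize={len(sub)}")
        lines.append("SampleData= {")
        for i in range(len(sub)):
            fields = []
            for locus, copy in cols:
                v = sub.alleles.at[i, locus]
                if copy >= 0:  # multi-copy locus
                    fields.append("?" if v is None else _format_allele(v[copy]))
                else:
                    if isinstance(v, tuple):
                        raise ValueError(
                            f"row {sub.sample_ids[i]!r}: duplication record at {locus} "
                            "cannot be represented in .arp; filter duplicated alleles first"
                        )
                    fields.append("?" if v is None else _format_allele(v))
            lines.append(f"{sub.sample_ids[i]} 1 " + " ".join(fields))
        lines.append("}")
    path.write_text("\n".join(lines) + "\n")


def read_arlequin(path: str | Path, panel: KitPanel) -> HaplotypeTable:
    """Parse an ``.arp`` haplotypic project written by :func:`export_table`."""
    text = Path(path).read_text()
    cols = _marker_columns(panel)
    sample_ids: list[str] = []
    populations: list[str] = []
    rows: list[list] = []
    pop = None
    in_block = False
    for raw in text.splitlines():
        line = raw.strip()
        if line.startswith("SampleName="):
            pop = line.split("=", 1)[1].strip().strip('"')
        elif line.startswith("SampleData"):
            in_block = True
        elif line == "}":
            in_block = False
        elif in_block and line:
            fields = line.split()
            sid, _freq, alleles = fields[0], fields[1], fields[2:]
            if len(alleles) != len(cols):
                raise ValueError(f"row {sid!r}: expected {len(cols)} allele fields, got {len(alleles)}")
            sample_ids.append(sid)
            populations.append(pop or "?")
            row: dict[str, object] = {}
            for (locus, copy), tok in zip(cols, alleles):
                val = None if tok == "?" else validate_allele(float(tok))
                if copy >= 0:
                    pair = row.get(locus)
                    if copy == 0:
                        row[locus] = (val,)
                    else:
                        first = pair[0] if isinstance(pair, tuple) else None
                        row[locus] = (
                            None
                            if first is None or val is None
                            else tuple(sorted((first, val)))
                        )
                else:
                    row[locus] = val
            rows.append([row[l] for l in panel.loci])
    alleles_df = pd.DataFrame(rows, columns=list(panel.loci), dtype=object)
    return HaplotypeTable(sample_ids, populations, alleles_df, panel)
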