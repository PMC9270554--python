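"""Readers and writers for the pipeline's file formats.

Text formats: CSV event tables (header FSC,SSC,FL1,FL2,FL3), tidy TSV
quadrant/fa tables, TSV expression matrices (genes as rows, first column the
gene id), two-column label TSVs, GMT gene sets, one-gene-per-line panels,
and JSON reports.  Binary: a minimal FCS 3.0/3.1 list-mode reader (float or
integer data, both byte orders) plus a float32 writer used for round-trip
testing; acquisition parameters are mapped onto the pipeline's FSC/SSC/FL1/
FL2/FL3 channels through an explicit channel map.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dose_response import CITable, DoseResponseSeries, MedianEffectFit
from .enrichment import ExpressionMatrix, GeneSet
from .flow import CHANNELS, EventTable, QuadrantSummary
from .signature import CohortClustering, ContingencyResult, SignaturePanel


# ---------------------------------------------------------------------------
# event tables
# ---------------------------------------------------------------------------

def write_event_table(events: EventTable, path: str | Path) -> None:
    events.data.to_csv(path, index=False)


def read_event_table(
    path: str | Path,
    format: str = "csv",
    channel_map: Mapping[str, str] | None = None,
    **meta,
) -> EventTable:
    """Load an event table from CSV or FCS.

    FCS mode requires ``channel_map`` naming which acquisition parameter
    ($PnN short name) corresponds to each of FL1/FL2/FL3 (FSC/SSC may be
    omitted when the FCS parameter is already named FSC/SSC).  ``meta``
    passes through EventTable metadata (drug, dose, environment, ...).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        df = pd.read_csv(path, float_precision="round_trip")
        for col in CHANNELS:
            if col not in df.columns:
                raise ValueError(f"{path}: missing channel column {col}")
            bad = pd.to_numeric(df[col], errors="coerce").isna()
            if bad.any():
                raise ValueError(
                    f"{path}: non-numeric value in column {col} at row "
                    f"{int(bad.idxmax())}"
                )
        return EventTable(data=df, **meta)
    if format == "fcs":
        df, params = _read_fcs(path)
        cmap = dict(channel_map or {})
        cols = {}
        for ch in CHANNELS:
            source = cmap.get(ch, ch)
            if source not in df.columns:
                raise ValueError(
                    f"{path}: channel {ch} not mapped to any FCS parameter; "
                    f"available parameters: {list(df.columns)}"
                )
            cols[ch] = df[source]
        return EventTable(data=pd.DataFrame(cols), **meta)
    raise ValueError(f"unknown format {format!r}")


def _read_fcs(path: Path) -> tuple[pd.DataFrame, dict]:
    """Minimal FCS 3.0/3.1 list-mode parser."""
    raw = path.read_bytes()
    version = raw[:6].decode("ascii", "replace")
    if not version.startswith("FCS3"):
        raise ValueError(f"{path}: unsupported FCS version {version!r}")
    text_start = int(raw[10:18])
    text_end = int(raw[18:26])
    text = raw[text_start : text_end + 1].decode("latin-1")
    delim = text[0]
    fields = text.strip(delim).split(delim)
    kw = {k.upper(): v for k, v in zip(fields[::2], fields[1::2])}
    if kw.get("$MODE", "L") != "L":
        raise ValueError(f"{path}: only list-mode ($MODE L) FCS is supported")
    par = int(kw["$PAR"])
    tot = int(kw["$TOT"])
    names = [kw.get(f"$P{i}N", f"P{i}") for i in range(1, par + 1)]
    datatype = kw.get("$DATATYPE", "F")
    byteord = kw.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"
    data_start = int(kw.get("$BEGINDATA") or raw[26:34])
    data_end = int(kw.get("$ENDDATA") or raw[34:42])
    if datatype == "F":
        dt = np.dtype(endian + "f4")
    elif datatype == "D":
        dt = np.dtype(endian + "f8")
    elif datatype == "I":
        bits = {int(kw[f"$P{i}B"]) for i in range(1, par + 1)}
        if len(bits) != 1 or bits.pop() not in (16, 32):
            raise ValueError(f"{path}: only uniform 16/32-bit integer data supported")
        nbits = int(kw["$P1B"])
        dt = np.dtype(endian + ("u2" if nbits == 16 else "u4"))
    else:
        raise ValueError(f"{path}: unsupported $DATATYPE {datatype!r}")
    arr = np.frombuffer(raw[data_start : data_end + 1], dtype=dt)
    if arr.size != par * tot:
        raise ValueError(
            f"{path}: data segment holds {arr.size} values, expected {par * tot}"
        )
    return pd.DataFrame(arr.reshape(tot, par).astype(float), columns=names), kw


def write_fcs(events: EventTable, path: str | Path) -> None:
    """Write a minimal FCS 3.1 file (float32, little-endian, list mode)."""
    data = events.data.to_numpy(dtype="<f4")
    tot, par = data.shape
    payload = data.tobytes()
    text_start = 256

    def build_text(begin: int, end: int) -> bytes:
        pairs = {
            "$MODE": "L",
            "$DATATYPE": "F",
            "$BYTEORD": "1,2,3,4",
            "$PAR": str(par),
            "$TOT": str(tot),
            "$BEGINDATA": str(begin).zfill(12),
            "$ENDDATA": str(end).zfill(12),
            "$BEGINANALYSIS": "0",
            "$ENDANALYSIS": "0",
            "$BEGINSTEXT": "0",
            "$ENDSTEXT": "0",
            "$NEXTDATA": "0",
        }
        for i, ch in enumerate(events.data.columns, start=1):
            pairs[f"$P{i}N"] = str(ch)
            pairs[f"$P{i}B"] = "32"
            pairs[f"$P{i}E"] = "0,0"
            pairs[f"$P{i}R"] = str(int(np.ceil(events.data[ch].max())) + 1)
        body = "/" + "/".join(f"{k}/{v}" for k, v in pairs.items()) + "/"
        return body.encode("ascii")

    # offsets padded to fixed width, so text length is offset-independent
    text = build_text(0, 0)
    data_start = text_start + len(text)
    data_end = data_start + len(payload) - 1
    text = build_text(data_start, data_end)
    header = b"FCS3.1    " + (
        f"{text_start:8d}{text_start + len(text) - 1:8d}"
        f"{data_start:8d}{data_end:8d}{0:8d}{0:8d}"
    ).encode("ascii")
    out = bytearray(b" " * data_start)
    out[: len(header)] = header
    out[text_start : text_start + len(text)] = text
    out += payload
    Path(path).write_bytes(bytes(out))


# ---------------------------------------------------------------------------
# tidy summaries and dose-response series
# ---------------------------------------------------------------------------

def write_summary_table(summaries: Sequence[QuadrantSummary], path: str | Path) -> None:
    pd.DataFrame([s.to_row() for s in summaries]).to_csv(path, sep="\t", index=False)


def read_series(path: str | Path, drug: str | None = None, environment: str | None = None) -> DoseResponseSeries:
    """Read a tidy TSV (dose, fa[, n_events, drug, environment, ...]) into a
    dose-response series, optionally filtering on drug/environment."""
    df = pd.read_csv(path, sep="\t")
    if drug is not None and "drug" in df.columns:
        df = df[df["drug"] == drug]
    if environment is not None and "environment" in df.columns:
        df = df[df["environment"] == environment]
    cols = ["dose", "fa"] + (["n_events"] if "n_events" in df.columns else [])
    if drug is None:
        drug = str(df["drug"].iloc[0]) if "drug" in df.columns else "drug"
    return DoseResponseSeries(
        records=df[cols].reset_index(drop=True),
        drug=drug,
        environment=environment or "normoxia",
    )


def write_fit_report(
    fit: MedianEffectFit, path: str | Path, levels: Sequence[float] = (0.5, 0.75, 0.9)
) -> None:
    report = {
        "m": fit.m,
        "Dm": fit.Dm,
        "r": fit.r,
        "n_points": fit.n_points,
        "excluded": [list(x) for x in fit.excluded],
        "warning": fit.warning,
        "ec": {str(l): fit.dose_for_effect(l) for l in levels}
        if fit.warning is None
        else {},
    }
    Path(path).write_text(json.dumps(report, indent=2) + "\n")


def write_ci_table(ci: CITable, path: str | Path) -> None:
    ci.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression matrices, gene sets, panels, labels
# ---------------------------------------------------------------------------

def write_matrix(matrix: ExpressionMatrix, path: str | Path, gene_col: str = "gene") -> None:
    matrix.values.rename_axis(gene_col).to_csv(path, sep="\t")


def read_labels(path: str | Path) -> pd.Series:
    """Two-column TSV (sample_id, label) -> Series indexed by sample."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: label file needs two columns (sample_id, label)")
    return pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0], name="label")


def write_labels(labels: pd.Series, path: str | Path) -> None:
    labels.rename_axis("sample_id").rename("label").to_csv(path, sep="\t")


def read_matrix(
    path: str | Path,
    mode: str = "counts",
    labels: pd.Series | None = None,
    labels_path: str | Path | None = None,
) -> ExpressionMatrix:
    """TSV matrix (genes as rows, first column gene ids) + group labels."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique()
        raise ValueError(f"{path}: duplicate gene ids: {list(dups[:5])}")
    if labels is None:
        if labels_path is None:
            raise ValueError("labels or labels_path required to build an ExpressionMatrix")
        labels = read_labels(labels_path)
    return ExpressionMatrix(values=df, groups=labels, mode=mode)


def read_gmt(path: str | Path) -> list[GeneSet]:
    sets = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{ln}: GMT line needs >=3 tab-separated fields "
                    f"(name, description, members), got {len(fields)}"
                )
            sets.append(
                GeneSet(name=fields[0], description=fields[1], genes=tuple(fields[2:]))
            )
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description or "-", *gs.genes]) + "\n")


def read_panel(path: str | Path, name: str | None = None) -> SignaturePanel:
    """Panel file: one gene id per line, or a single GMT record."""
    path = Path(path)
    lines = [l.strip() for l in path.read_text().splitlines() if l.strip()]
    if not lines:
        raise ValueError(f"{path}: empty panel file")
    if "\t" in lines[0]:
        gs = read_gmt(path)[0]
        return SignaturePanel(name=name or gs.name, genes=gs.genes)
    return SignaturePanel(name=name or path.stem, genes=tuple(lines))


# ---------------------------------------------------------------------------
# clustering outputs
# ---------------------------------------------------------------------------

def write_assignments(
    clustering: CohortClustering,
    labels: pd.Series,
    path: str | Path,
    merge_map: Mapping[int, str] | None = None,
) -> None:
    out = pd.DataFrame(
        {
            "sample": clustering.assignments.index,
            "cluster": clustering.assignments.to_numpy(),
            "merged_group": clustering.merged(merge_map or {}).to_numpy(),
            "clinical_label": labels.reindex(clustering.assignments.index).to_numpy(),
        }
    )
    out.to_csv(path, sep="\t", index=False)


def write_contingency(result: ContingencyResult, path: str | Path) -> None:
    payload = {
        "table": {str(r): result.table.loc[r].to_dict() for r in result.table.index},
        "chi2": result.chi2,
        "df": result.df,
        "p": result.p,
        "row_pct": {str(r): result.row_pct.loc[r].round(4).to_dict() for r in result.row_pct.index},
        "col_pct": {str(r): result.col_pct.loc[r].round(4).to_dict() for r in result.col_pct.index},
        "unreliable": result.unreliable,
        "mc_p": result.mc_p,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def dendrogram_newick(clustering: CohortClustering) -> str:
    """Serialize the linkage tree as a Newick string with merge heights as
    branch lengths and sample ids at the leaves."""
    from scipy.cluster.hierarchy import to_tree

    tree = to_tree(clustering.linkage)
    names = list(clustering.assignments.index)

    def rec(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{names[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    inner = rec(tree, tree.dist)
    return inner.rsplit(":", 1)[0] + ";"
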