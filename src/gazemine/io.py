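"""File formats: gaze CSV, case manifest, model and report exports."""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

from .mining import PatternSet, PatternStatistics
from .preprocessing import GAZE_COLUMNS, CaseMeta
from .temporal import MarkovModel

__all__ = [
    "read_gaze_csv",
    "write_gaze_csv",
    "load_manifest",
    "write_graphml",
    "write_markov_json",
    "read_markov_json",
    "write_pattern_report",
    "write_pattern_statistics_tsv",
]


def read_gaze_csv(path: str | Path) -> pd.DataFrame:
    """Read a raw gaze stream (columns ``t_ms,x_px,y_px,valid``)."""
    df = pd.read_csv(path)
    missing = [c for c in GAZE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: gaze CSV missing columns {missing}")
    df["valid"] = df["valid"].astype(bool)
    return df[list(GAZE_COLUMNS)]


def write_gaze_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format="%.4f")


def load_manifest(path: str | Path) -> list[tuple[CaseMeta, Path, Path]]:
    """Load a case manifest: ``case_id -> {gaze_file, roi_file, viewer_id,
    group, task}``.  Relative file paths resolve against the manifest's
    directory.  Returns (meta, gaze_path, roi_path) per case."""
    path = Path(path)
    base = path.parent
    with open(path) as fh:
        entries = json.load(fh)
    out = []
    for case_id, rec in entries.items():
        meta = CaseMeta(
            case_id=case_id,
            viewer_id=rec.get("viewer_id", ""),
            group_id=rec["group"],
            task_id=rec.get("task", ""),
        )
        out.append((meta, base / rec["gaze_file"], base / rec["roi_file"]))
    return out


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, str(path))


def write_markov_json(model: MarkovModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=1))


def read_markov_json(path: str | Path) -> MarkovModel:
    return MarkovModel.from_dict(json.loads(Path(path).read_text()))


def write_pattern_report(pattern_sets: Iterable[PatternSet], path: str | Path) -> None:
    """JSON array of mined patterns; infinite growth serialized as "inf"."""
    records = []
    for ps in pattern_sets:
        for p in ps:
            records.append(
                {
                    "tokens": list(p.tokens),
                    "kind": p.kind,
                    "group": p.source_group,
                    "supp_own": p.supp_own,
                    "supp_other": p.supp_other,
                    "growth": "inf" if math.isinf(p.growth) else p.growth,
                    "length": len(p),
                }
            )
    Path(path).write_text(json.dumps(records, indent=1))


def write_pattern_statistics_tsv(
    stats: dict[str, PatternStatistics], path: str | Path
) -> None:
    """One row per pattern set with the summary-statistics columns."""
    rows = []
    for name, st in stats.items():
        rows.append(
            {
                "set": name,
                "n_seq": st.n_patterns,
                "mean_len": st.mean_length,
                "max_len": st.max_length,
                "d_lev": st.mean_pairwise_lev,
                "d_roi": st.mean_pairwise_roi,
                "mean_supp": st.mean_support,
                "pct_uniq": st.pct_unique,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.4f")
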