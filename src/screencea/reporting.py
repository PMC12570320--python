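"""Report assembly: results-table rendering and run manifests."""

from __future__ import annotations

import datetime as _dt
import json
import hashlib
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .economics import ArmResult, CEAResult
from .params import STAGES


def _arm_rows(arm: ArmResult) -> dict[str, float]:
    rows = {
        "Lung cancer diagnoses, total": arm.diagnoses_total,
        "  Stage 0": arm.diagnoses_stage0,
    }
    for s in STAGES:
        rows[f"  Diagnoses stage {s}"] = arm.diagnoses_by_stage.get(s, 0.0)
    rows["Lung cancer deaths, total"] = arm.deaths_total
    for s in STAGES:
        rows[f"  Deaths stage {s}"] = arm.deaths_by_stage.get(s, 0.0)
    rows["Life years, total (disc.)"] = arm.ly_disc
    for s in STAGES:
        rows[f"  LY stage {s}"] = arm.ly_by_stage.get(s, 0.0)
    rows["  LY LC-free participants"] = arm.ly_lc_free
    rows["QALYs, total (disc.)"] = arm.qaly_disc
    for s in STAGES:
        rows[f"  QALY stage {s}"] = arm.qaly_by_stage.get(s, 0.0)
    rows["  QALY LC-free participants"] = arm.qaly_lc_free
    rows["Costs, total (US$)"] = arm.total_cost
    rows["  Screening costs"] = arm.screening_cost
    rows["  Diagnostic costs"] = arm.diagnostic_cost
    rows["  Treatment costs"] = arm.treatment_cost
    for s in STAGES:
        rows[f"    Treatment stage {s}"] = arm.treatment_cost_by_stage.get(s, 0.0)
    return rows


def cea_table(result: CEAResult) -> pd.DataFrame:
    """Three-column (screening / no screening / incremental) results table
    for one cohort; the incremental column is the recomputed arm difference
    for every row."""
    s_rows = _arm_rows(result.screening)
    n_rows = _arm_rows(result.no_screening)
    df = pd.DataFrame(
        {
            "screening": s_rows,
            "no_screening": n_rows,
        }
    )
    df["incremental"] = df["screening"] - df["no_screening"]
    extra = pd.DataFrame(
        {
            "screening": {"ICER per QALY (US$)": float("nan"), "ICER per LYG (US$)": float("nan"),
                          "NMB at WTP low": float("nan"), "NMB at WTP high": float("nan")},
            "no_screening": {"ICER per QALY (US$)": float("nan"), "ICER per LYG (US$)": float("nan"),
                             "NMB at WTP low": float("nan"), "NMB at WTP high": float("nan")},
            "incremental": {
                "ICER per QALY (US$)": result.icer_per_qaly.raw,
                "ICER per LYG (US$)": result.icer_per_lyg.raw,
                "NMB at WTP low": result.nmb_low,
                "NMB at WTP high": result.nmb_high,
            },
        }
    )
    return pd.concat([df, extra])


def render_table3(result_smoking: CEAResult | None, result_nonsmoking: CEAResult | None) -> str:
    """Two-cohort base-case report in the three-column layout."""
    parts = []
    for label, res in (("smoking-history cohort", result_smoking),
                       ("risk-factor (non-smoking) cohort", result_nonsmoking)):
        if res is None:
            continue
        df = cea_table(res)
        parts.append(f"Base-case results - {label}\n" + df.to_string(float_format=lambda v: f"{v:,.1f}"))
    return "\n\n".join(parts)


@dataclass
class RunManifest:
    command: str
    config_path: str
    config_sha256: str
    seed: int | None
    version: str
    timestamp: str
    outputs: list[str]


def write_manifest(
    command: str,
    config_path: str | Path | None,
    outputs: list[str | Path],
    seed: int | None = None,
    directory: str | Path = ".",
) -> Path:
    """Write a manifest JSON next to a run's outputs."""
    if config_path is not None:
        digest = hashlib.sha256(Path(config_path).read_bytes()).hexdigest()
    else:
        digest = ""
    m = RunManifest(
        command=command,
        config_path=str(config_path) if config_path else "",
        config_sha256=digest,
        seed=seed,
        version=__version__,
        timestamp=_dt.datetime.now(_dt.timezone.utc).isoformat(),
        outputs=[str(o) for o in outputs],
    )
    path = Path(directory) / f"manifest_{command}.json"
    path.write_text(json.dumps(asdict(m), indent=2) + "\n")
    return path
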