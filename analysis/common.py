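"""Shared configuration for the numbered analysis scripts.

All scripts regenerate the same synthetic study deterministically from
one master seed, so each is runnable on its own; heavier null-model
stages run at 199 nulls.  Tables and trees are written to scratch/ (bulk
data), summaries to results/.
"""

from __future__ import annotations

import json
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

CONFIG = {
    "seed": 20250925,
    "synth": {"reads_per_sample": 20000},
    "n_null_assembly": 199,
    "n_perm_niche": 1000,
    "n_perm_permanova": 999,
}

_cache: dict = {}


def pipeline_results() -> dict:
    """Run (once per process) the full pipeline at the analysis config."""
    if "results" not in _cache:
        from phyllokbs import run_pipeline

        RESULTS.mkdir(exist_ok=True)
        SCRATCH.mkdir(exist_ok=True)
        _cache["results"] = run_pipeline(dict(CONFIG), out_dir=SCRATCH / "pipeline")
    return _cache["results"]


def save(name: str, payload: dict) -> Path:
    RESULTS.mkdir(exist_ok=True)
    path = RESULTS / name
    path.write_text(json.dumps(payload, indent=2, default=float))
    print(f"  -> wrote {path.relative_to(ROOT)}")
    return path
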