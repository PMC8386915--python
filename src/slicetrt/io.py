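"""File formats and run manifests.

Responses: CSV, UTF-8, comma-separated, mandatory header row of item labels,
one row per person, cells 0/1.  Testlet design: JSON object
``{"testlets": {"1": [1, 2, ...], ...}}`` with 1-based item indices.  Draws:
one CSV per chain (columns = parameter labels, rows = stored iterations) with
a JSON manifest carrying the seed, configuration and a design hash.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .model import PriorConfig, TestletDesign, validate_responses
from .sampler import MCMCConfig, PosteriorDraws

__all__ = [
    "read_responses", "write_responses", "read_design", "write_design",
    "design_hash", "write_run", "read_run", "draws_to_frame", "frame_to_draws",
]


def read_responses(path) -> tuple[np.ndarray, list[str]]:
    """Read a binary response matrix; returns ``(Y, item_labels)``.

    Rejects ragged rows and non-binary cells, naming the offending
    row/column in the error.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().strip()
        if not header:
            raise ValueError(f"{path}: empty file")
        labels = [c.strip() for c in header.split(",")]
        rows = []
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            cells = line.split(",")
            if len(cells) != len(labels):
                raise ValueError(
                    f"{path}: line {lineno} has {len(cells)} cells, expected {len(labels)}"
                )
            row = []
            for col, cell in enumerate(cells, start=1):
                v = cell.strip()
                if v not in ("0", "1"):
                    raise ValueError(
                        f"{path}: non-binary cell {v!r} at line {lineno}, column {col}"
                    )
                row.append(int(v))
            rows.append(row)
    if not rows:
        raise ValueError(f"{path}: no response rows")
    return validate_responses(np.array(rows)), labels


def write_responses(path, Y, labels=None) -> None:
    Y = validate_responses(Y)
    labels = labels or [f"item{j + 1}" for j in range(Y.shape[1])]
    pd.DataFrame(Y, columns=labels).to_csv(path, index=False)


def read_design(path) -> TestletDesign:
    with Path(path).open("r", encoding="utf-8") as fh:
        payload = json.load(fh)
    if "testlets" not in payload or not isinstance(payload["testlets"], dict):
        raise ValueError(f"{path}: expected a JSON object with a 'testlets' mapping")
    return TestletDesign.from_groups(payload["testlets"])


def write_design(path, design: TestletDesign) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump({"testlets": design.to_groups()}, fh, indent=1)


def design_hash(design: TestletDesign) -> str:
    canon = json.dumps(design.to_groups(), sort_keys=True).encode()
    return hashlib.sha256(canon).hexdigest()[:16]


def draws_to_frame(draws: PosteriorDraws) -> pd.DataFrame:
    """Wide per-iteration table with 1-based parameter labels."""
    from .diagnostics import _scalar_series

    return pd.DataFrame({label: series for label, series in _scalar_series(draws)})


_LABEL = re.compile(r"^(a|b|theta)\[(\d+)\]$|^eta\[(\d+),(\d+)\]$"
                    r"|^sigma2_eta\[(\d+)\]$|^(sigma2_a|sigma2_b)$")


def frame_to_draws(df: pd.DataFrame, model: str = "n2pltm",
                   seed=None) -> PosteriorDraws:
    """Rebuild a ``PosteriorDraws`` from a draw table written by this module."""
    dims = {"a": 0, "b": 0, "theta": 0, "eta_i": 0, "eta_k": 0, "s2eta": 0}
    for col in df.columns:
        m = _LABEL.match(col)
        if m is None:
            raise ValueError(f"unrecognized draw column {col!r}")
        if m.group(1):
            key = {"a": "a", "b": "b", "theta": "theta"}[m.group(1)]
            dims[key] = max(dims[key], int(m.group(2)))
        elif m.group(3):
            dims["eta_i"] = max(dims["eta_i"], int(m.group(3)))
            dims["eta_k"] = max(dims["eta_k"], int(m.group(4)))
        elif m.group(5):
            dims["s2eta"] = max(dims["s2eta"], int(m.group(5)))
    M = len(df)
    eta = np.zeros((M, dims["eta_i"], dims["eta_k"]))
    for i in range(dims["eta_i"]):
        for k in range(dims["eta_k"]):
            eta[:, i, k] = df[f"eta[{i + 1},{k + 1}]"].to_numpy()
    return PosteriorDraws(
        a=np.column_stack([df[f"a[{j + 1}]"] for j in range(dims["a"])]),
        b=np.column_stack([df[f"b[{j + 1}]"] for j in range(dims["b"])]),
        theta=np.column_stack([df[f"theta[{i + 1}]"] for i in range(dims["theta"])]),
        eta=eta,
        sigma2_a=df["sigma2_a"].to_numpy(),
        sigma2_b=df["sigma2_b"].to_numpy(),
        sigma2_eta=np.column_stack(
            [df[f"sigma2_eta[{k + 1}]"] for k in range(dims["s2eta"])])
        if dims["s2eta"] else np.zeros((M, 0)),
        model=model, seed=seed,
    )


def write_run(out_dir, chains: list[PosteriorDraws], design: TestletDesign,
              config: MCMCConfig, model: str) -> Path:
    """Write per-chain draw CSVs plus the run manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chain_files = []
    for c, draws in enumerate(chains, start=1):
        fname = f"chain_{c}.csv"
        draws_to_frame(draws).to_csv(out_dir / fname, index=False)
        chain_files.append(fname)
    manifest = {
        "model": model,
        "seed": config.seed,
        "config": {
            "iterations": config.iterations, "burn_in": config.burn_in,
            "chains": config.chains, "thinning": config.thinning,
            "start": config.start, "prior": asdict(config.prior),
        },
        "design": design.to_groups(),
        "design_hash": design_hash(design),
        "created": datetime.now(timezone.utc).isoformat(),
        "chain_files": chain_files,
    }
    mpath = out_dir / "manifest.json"
    with mpath.open("w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)
    return mpath


def read_run(run_dir) -> tuple[list[PosteriorDraws], dict]:
    """Load the chains and manifest written by :func:`write_run`."""
    run_dir = Path(run_dir)
    with (run_dir / "manifest.json").open("r", encoding="utf-8") as fh:
        manifest = json.load(fh)
    chains = [
        frame_to_draws(pd.read_csv(run_dir / fname), model=manifest["model"],
                       seed=manifest["seed"])
        for fname in manifest["chain_files"]
    ]
    return chains, manifest
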