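"""Plain-text I/O: TSV time-series, CSV TPMs, JSON manifests.

Time-series files are TSV with a header row of region labels and one
row per time point; binary series round-trip losslessly and continuous
series keep full float precision.  TPMs are CSV with little-endian state
indices as headers.  Cohorts are written one file per (network,
condition, subject) plus a JSON manifest recording the spec, seeds and
generative TPM paths.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import BinaryTimeSeries, RegionTimeSeries, Segment
from .states import StateByStateTPM
from .synthetic import CohortData


def write_series(series, path) -> None:
    """Write a binary or continuous series as TSV with a label header."""
    path = Path(path)
    df = pd.DataFrame(series.values, columns=series.region_labels)
    # pandas' default float repr is shortest-round-trip: lossless
    df.to_csv(path, sep="\t", index=False)
    if _is_binary(series) and len(series.provenance) > 1:
        meta = [{"subject": s.subject, "start": s.start, "length": s.length}
                for s in series.provenance]
        path.with_suffix(path.suffix + ".segments.json").write_text(
            json.dumps(meta))


def _is_binary(series) -> bool:
    return isinstance(series, BinaryTimeSeries)


def read_series(path, binary: bool = True, tr_seconds: float = 2.0):
    """Read a TSV series; parse errors name the offending row/column.

    ``binary=True`` validates {0, 1} entries and returns a
    BinaryTimeSeries (restoring segment provenance if a sidecar exists);
    otherwise returns a RegionTimeSeries.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file") from None
    if df.shape[0] == 0:
        raise ValueError(f"{path}: header-only file, no time points")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(f"{path}: non-numeric cell at data row "
                             f"{row + 1}, column {col!r}")
    if df.isna().any().any():
        raise ValueError(f"{path}: missing values")
    values = df.to_numpy()
    labels = list(df.columns)
    if not binary:
        return RegionTimeSeries(values.astype(float), labels, tr_seconds)
    nonbin = ~np.isin(values, (0, 1))
    if nonbin.any():
        r, c = np.argwhere(nonbin)[0]
        raise ValueError(f"{path}: non-binary value at data row {r + 1}, "
                         f"column {labels[c]!r}")
    segments = None
    sidecar = path.with_suffix(path.suffix + ".segments.json")
    if sidecar.exists():
        segments = [Segment(d["subject"], d["start"], d["length"])
                    for d in json.loads(sidecar.read_text())]
    return BinaryTimeSeries(values.astype(np.int8), labels, segments or [])


def write_tpm(tpm: StateByStateTPM, path) -> None:
    n = tpm.probs.shape[0]
    pd.DataFrame(tpm.probs, index=range(n), columns=range(n)).to_csv(
        path, float_format="%.17g")


def read_tpm(path) -> StateByStateTPM:
    df = pd.read_csv(path, index_col=0)
    return StateByStateTPM(df.to_numpy())


def write_cohort(cohort: CohortData, outdir) -> Path:
    """Write every series as TSV plus a JSON manifest; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = cohort.spec
    entries = []
    for (net, cond, subj), series in cohort.series.items():
        fname = f"{net}_{cond}_s{subj:02d}.tsv"
        write_series(series, outdir / fname)
        entries.append({"network": net, "condition": cond,
                        "subject": subj, "file": fname})
    tpm_files = {}
    for (net, cond), gt in cohort.generative.items():
        fname = f"tpm_{net}_{cond}.csv"
        write_tpm(gt.tpm, outdir / fname)
        tpm_files[f"{net}|{cond}"] = {
            "file": fname, "coupling": gt.coupling_strength}
    manifest = {
        "spec": {
            "subjects": spec.subjects,
            "conditions": list(spec.conditions),
            "n_timepoints": spec.n_timepoints,
            "n_nodes": spec.n_nodes,
            "networks": {k: list(v) for k, v in spec.networks.items()},
            "modulation_profile": list(spec.modulation_profile),
            "tr_seconds": spec.tr_seconds,
            "seed": spec.seed,
        },
        "series": entries,
        "generative_tpms": tpm_files,
    }
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1))
    return mpath
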