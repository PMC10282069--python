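"""Reading and writing OTU tables and fitted-model artifacts.

Two table dialects are supported:

* tab-separated OTU × sample text, sample columns named ``subject:day``
  (or with a sidecar metadata table mapping sample names to subject and
  day), optional ``taxonomy`` column of semicolon-separated lineages;
* BIOM 1.0 JSON (dense or sparse), with subject/day taken from sample
  metadata when present, else parsed from the sample id.

Model artifacts are plain tab-separated tables plus a JSON diagnostics
sidecar, written at 15 significant digits so that a read-back reproduces
the fitted objects at stored precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import CountTensor

__all__ = [
    "read_otu_table",
    "write_otu_table",
    "write_model_artifacts",
    "read_model_artifacts",
]

_FLOAT_FMT = "%.15g"


def read_otu_table(
    path, sample_meta_path=None, dialect: str | None = None
) -> CountTensor:
    """Read an OTU table (TSV or BIOM-JSON) into a CountTensor.

    ``dialect`` is ``"tsv"`` or ``"biom"``; inferred from the file when
    omitted (a leading ``{`` or a ``.biom`` suffix means BIOM JSON).
    """
    path = Path(path)
    if dialect is None:
        if path.suffix == ".biom":
            dialect = "biom"
        else:
            with open(path) as fh:
                dialect = "biom" if fh.read(1) == "{" else "tsv"
    if dialect == "biom":
        return _read_biom_json(path)
    table = pd.read_csv(path, sep="\t", index_col=0)
    meta = None
    if sample_meta_path is not None:
        meta = pd.read_csv(sample_meta_path, sep="\t", index_col=0)
    return CountTensor.from_dataframe(table, sample_meta=meta)


def _read_biom_json(path) -> CountTensor:
    with open(path) as fh:
        doc = json.load(fh)
    n_rows, n_cols = doc["shape"]
    data = np.zeros((n_rows, n_cols))
    if doc.get("matrix_type") == "dense":
        data[:] = np.asarray(doc["data"], float)
    else:
        for r, c, v in doc["data"]:
            data[int(r), int(c)] = v
    otu_ids = [row["id"] for row in doc["rows"]]
    taxonomy = None
    if all(row.get("metadata") and "taxonomy" in row["metadata"]
           for row in doc["rows"]):
        taxonomy = [
            ";".join(row["metadata"]["taxonomy"])
            if isinstance(row["metadata"]["taxonomy"], list)
            else str(row["metadata"]["taxonomy"])
            for row in doc["rows"]
        ]
    cols = []
    for col in doc["columns"]:
        md = col.get("metadata") or {}
        if "subject" in md and "day" in md:
            cols.append(f"{md['subject']}:{int(md['day'])}")
        else:
            cols.append(col["id"])
    df = pd.DataFrame(data, index=otu_ids, columns=cols)
    if taxonomy is not None:
        df["taxonomy"] = taxonomy
    return CountTensor.from_dataframe(df)


def write_otu_table(data: CountTensor, path) -> None:
    """Write observed samples as a tab-separated OTU × sample table."""
    df = data.to_dataframe()
    int_like = np.allclose(df.drop(columns=["taxonomy"], errors="ignore")
                           .to_numpy(float) % 1, 0)
    if int_like:
        num = df.drop(columns=["taxonomy"], errors="ignore").astype(int)
        for c in num.columns:
            df[c] = num[c]
    df.to_csv(path, sep="\t", index_label="otu_id")


# ----------------------------------------------------------------------
def write_model_artifacts(out_dir, ecn_results, extra_diagnostics=None) -> dict:
    """Write the fitted-model artifact set; returns {name: path}.

    Files (all tab-separated with headers, 15 significant digits):
    ``ecns.tsv`` (T × K mode trajectories), ``loadings_<subject>.tsv``
    (K × O per subject), ``eigenvalues.tsv``, ``rotation.tsv``,
    ``dynamics_A.tsv``, ``baseline.tsv``, and ``diagnostics.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    res = ecn_results.results
    data = res.model.data if res is not None else None
    T, K = ecn_results.y.shape
    modes = [f"ECN{k + 1}" for k in range(K)]
    files: dict[str, Path] = {}

    days = data.time_stamps if data is not None else np.arange(T)
    ecn_df = pd.DataFrame(ecn_results.y, columns=modes,
                          index=pd.Index(days, name="day"))
    files["ecns"] = out / "ecns.tsv"
    ecn_df.to_csv(files["ecns"], sep="\t", float_format=_FLOAT_FMT)

    subj_ids = (
        list(data.subject_ids) if data is not None
        else [f"s{i}" for i in range(ecn_results.phi.shape[2])]
    )
    otu_ids = (
        list(data.otu_ids) if data is not None
        else [f"otu{i}" for i in range(ecn_results.phi.shape[1])]
    )
    for s, subj in enumerate(subj_ids):
        df = pd.DataFrame(ecn_results.phi[:, :, s], index=modes,
                          columns=otu_ids)
        f = out / f"loadings_{subj}.tsv"
        files[f"loadings_{subj}"] = f
        df.to_csv(f, sep="\t", index_label="mode", float_format=_FLOAT_FMT)

    pd.DataFrame({"mode": modes,
                  "eigenvalue": ecn_results.eigenvalues,
                  "baseline": ecn_results.baseline}).to_csv(
        out / "eigenvalues.tsv", sep="\t", index=False,
        float_format=_FLOAT_FMT)
    files["eigenvalues"] = out / "eigenvalues.tsv"

    pd.DataFrame(ecn_results.rotation, index=modes,
                 columns=[f"z{k + 1}" for k in range(K)]).to_csv(
        out / "rotation.tsv", sep="\t", index_label="mode",
        float_format=_FLOAT_FMT)
    files["rotation"] = out / "rotation.tsv"

    pd.DataFrame(ecn_results.dynamics.A).to_csv(
        out / "dynamics_A.tsv", sep="\t", index=False,
        float_format=_FLOAT_FMT)
    files["dynamics_A"] = out / "dynamics_A.tsv"

    diag = {
        "k": K,
        "dynamics_method": ecn_results.dynamics.method,
        "dynamics_residual": ecn_results.dynamics.residual_error,
        "eigenvalues": [float(v) for v in ecn_results.eigenvalues],
    }
    if res is not None:
        diag.update({
            "seed": res.seed,
            "learning_rate": res.learning_rate,
            "tol": res.tol,
            "max_iter": res.max_iter,
            "n_iter": res.n_iter,
            "converged": res.converged,
            "rel_grad_z": res.rel_grad_z,
            "rel_grad_theta": res.rel_grad_theta,
            "loglike_final": float(res.loglike_trace[-1]),
            "loglike_trace_head": [float(v) for v in res.loglike_trace[:100]],
            "n_backtracks": res.n_backtracks,
        })
    if extra_diagnostics:
        diag.update(extra_diagnostics)
    files["diagnostics"] = out / "diagnostics.json"
    with open(files["diagnostics"], "w") as fh:
        json.dump(diag, fh, indent=1)
    return files


def read_model_artifacts(out_dir) -> dict:
    """Read artifacts back as arrays/frames (inverse of the writer)."""
    out = Path(out_dir)
    ecns = pd.read_csv(out / "ecns.tsv", sep="\t", index_col=0)
    eig = pd.read_csv(out / "eigenvalues.tsv", sep="\t")
    rot = pd.read_csv(out / "rotation.tsv", sep="\t", index_col=0)
    with open(out / "diagnostics.json") as fh:
        diag = json.load(fh)
    loadings = {}
    for f in sorted(out.glob("loadings_*.tsv")):
        subj = f.stem[len("loadings_"):]
        loadings[subj] = pd.read_csv(f, sep="\t", index_col=0)
    dyn = pd.read_csv(out / "dynamics_A.tsv", sep="\t")
    return {
        "ecns": ecns,
        "eigenvalues": eig,
        "rotation": rot,
        "loadings": loadings,
        "dynamics_A": dyn.to_numpy(),
        "diagnostics": diag,
    }
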