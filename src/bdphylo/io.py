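"""File input/output: newick trees, LTT tables, model configs, reports.

Conventions shared by every writer: TSV with a deterministic column
order, floats at 12 significant digits, and a ``#``-prefixed header that
echoes the seed and configuration needed to regenerate a stochastic
artifact.  Newick files store branch lengths (differences of ages); TSV
files store ages; the conversion between the two lives in
:func:`bdphylo.simulate.ltt_from_tree` and nowhere else.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .models import LTTData, ModelError, RateModel, model_from_dict, model_to_dict
from .simulate import ULTRAMETRIC_RTOL, ltt_from_tree

__all__ = [
    "read_newick",
    "write_newick",
    "read_ltt_tsv",
    "write_ltt_tsv",
    "write_fit_tsv",
    "write_surface_tsv",
    "load_model_json",
    "save_model_json",
]

_FLOAT_FMT = "%.12g"


def read_newick(path, rtol: float = ULTRAMETRIC_RTOL) -> dendropy.Tree:
    """Read a rooted, binary, ultrametric time tree from a newick file.

    Branch lengths must be present and in time units.  Comments are
    stripped with a warning; polytomies and non-ultrametric trees (beyond
    ``rtol`` x height, to tolerate rounding in real timetrees) raise
    :class:`~bdphylo.models.ModelError` with a per-tip deviation report.
    """
    text = Path(path).read_text()
    if "[" in text:
        warnings.warn("newick comments are ignored", stacklevel=2)
    tree = dendropy.Tree.get(
        data=text, schema="newick", suppress_internal_node_taxa=True
    )
    # validation + age computation happen in ltt_from_tree
    data = ltt_from_tree(tree, rtol=rtol)
    tree.ltt = data
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    """Write a tree as plain newick with branch lengths."""
    Path(path).write_text(
        tree.as_string(schema="newick", suppress_rooting=True,
                       real_value_format_specifier=".12g")
    )


def _header_lines(header: dict | None) -> str:
    if not header:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in header.items())


def write_ltt_tsv(data: LTTData, path, header: dict | None = None) -> None:
    """Write LTT data as 2-column TSV (node index, age), ages descending."""
    hdr = dict(header or {})
    if data.stem_age is not None:
        hdr["stem_age"] = _FLOAT_FMT % data.stem_age
    df = pd.DataFrame(
        {"node": np.arange(1, data.ages.size + 1), "age": data.ages}
    )
    with open(path, "w") as fh:
        fh.write(_header_lines(hdr))
        df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_ltt_tsv(path) -> LTTData:
    """Read LTT data written by :func:`write_ltt_tsv`."""
    stem = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("# stem_age:"):
                stem = float(line.split(":", 1)[1])
    df = pd.read_csv(path, sep="\t", comment="#")
    if "age" not in df.columns:
        raise ModelError(f"{path}: expected an 'age' column")
    return LTTData(df["age"].to_numpy(), stem_age=stem)


def write_fit_tsv(fit, path, header: dict | None = None) -> None:
    """Write a FitResult as TSV rows (parameter, estimate, std_error)."""
    hdr = dict(header or {})
    hdr["loglik_at_mle"] = _FLOAT_FMT % fit.loglik_at_mle
    hdr["convergence"] = fit.convergence.get("status", "unknown")
    if fit.non_identifiable:
        hdr["non_identifiable"] = ",".join(fit.non_identifiable)
    df = fit.summary().rename_axis("parameter").reset_index()
    with open(path, "w") as fh:
        fh.write(_header_lines(hdr))
        df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_surface_tsv(surface, path, header: dict | None = None) -> None:
    """Write a LikelihoodSurface in long format (lambda0, lambda1, loglik)."""
    with open(path, "w") as fh:
        fh.write(_header_lines(header))
        surface.to_frame().to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


def save_model_json(model: RateModel, path) -> None:
    """Serialize a (piecewise-)constant model spec; round-trips exactly."""
    Path(path).write_text(json.dumps(model_to_dict(model), indent=1) + "\n")


def load_model_json(path) -> RateModel:
    return model_from_dict(json.loads(Path(path).read_text()))
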