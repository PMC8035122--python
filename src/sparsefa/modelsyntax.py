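"""Measurement-model syntax, spec serialization, and data/config readers.

Model syntax is one line per factor::

    f1 =~ x1 + x2 + x3 + 0*x4
    f2 =~ 0.85*x5 + x6 + x7

A numeric prefix fixes the loading at that value (``0*`` fixes a zero; a
nonzero prefix declares a marker).  Unprefixed loadings are free and, by
default, penalized.  Variables never mentioned for a factor are fixed at
zero.  Identification defaults: with one group, unit factor variances; with
several groups, a marker per factor (the explicitly fixed nonzero loading,
or else the factor's first indicator fixed at 1) whose intercept is fixed at
zero, plus free intercepts (penalized toward cross-group equality), free
factor covariances and free factor means.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd
import yaml

from .model import FIXED, FREE, PENALIZED, DataSummary, ModelSpec

__all__ = [
    "ModelSyntaxError",
    "parse_model",
    "spec_to_dict",
    "spec_from_dict",
    "read_table",
    "read_sufficient",
    "read_config",
]


class ModelSyntaxError(ValueError):
    def __init__(self, message, line=None):
        super().__init__(message if line is None else f"line {line}: {message}")
        self.line = line


_TERM = re.compile(r"^(?:(?P<coef>[+-]?\d*\.?\d+(?:[eE][+-]?\d+)?)\*)?(?P<var>[A-Za-z_]\w*)$")


def parse_model(text, var_names, G=1, penalize_free=True):
    """Parse model-syntax text into a :class:`ModelSpec`."""
    var_names = list(var_names)
    p = len(var_names)
    factors: list[str] = []
    terms: dict[str, list] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=~" not in line:
            raise ModelSyntaxError(f"expected 'factor =~ indicators', got {line!r}", lineno)
        lhs, rhs = (s.strip() for s in line.split("=~", 1))
        if not re.match(r"^[A-Za-z_]\w*$", lhs):
            raise ModelSyntaxError(f"invalid factor name {lhs!r}", lineno)
        if lhs not in factors:
            factors.append(lhs)
            terms[lhs] = []
        for chunk in rhs.split("+"):
            chunk = chunk.strip()
            if not chunk:
                raise ModelSyntaxError("empty indicator term", lineno)
            mt = _TERM.match(chunk)
            if not mt:
                raise ModelSyntaxError(f"cannot parse term {chunk!r}", lineno)
            var = mt.group("var")
            if var not in var_names:
                raise ModelSyntaxError(f"unknown variable {var!r}", lineno)
            coef = mt.group("coef")
            terms[lhs].append((var, None if coef is None else float(coef), lineno))
    if not factors:
        raise ModelSyntaxError("no factors declared")
    r = len(factors)
    lam_code = np.full((p, r), FIXED)
    lam_fixed = np.zeros((p, r))
    for j, f in enumerate(factors):
        if not terms[f]:
            raise ModelSyntaxError(f"factor {f!r} has no indicators")
        fixed_nonzero = 0
        for var, coef, lineno in terms[f]:
            i = var_names.index(var)
            if coef is None:
                lam_code[i, j] = PENALIZED if penalize_free else FREE
            else:
                lam_code[i, j] = FIXED
                lam_fixed[i, j] = coef
                if coef != 0:
                    fixed_nonzero += 1
                    if fixed_nonzero > 1:
                        raise ModelSyntaxError(f"factor {f!r} has more than one marker", lineno)
    if G == 1:
        spec = ModelSpec(p=p, r=r, G=1, lam_code=lam_code, lam_fixed=lam_fixed,
                         var_names=var_names, factor_names=factors)
        spec.identification_check()
        return spec
    # multiple groups: marker-variable identification
    tau_code = np.full(p, PENALIZED)
    for j, f in enumerate(factors):
        has_marker = np.any((lam_code[:, j] == FIXED) & (lam_fixed[:, j] != 0))
        if not has_marker:
            var, coef, lineno = terms[f][0]
            i = var_names.index(var)
            if lam_code[i, j] == FIXED and lam_fixed[i, j] == 0:
                raise ModelSyntaxError(f"first indicator of factor {f!r} is fixed at zero; cannot be its marker")
            lam_code[i, j] = FIXED
            lam_fixed[i, j] = 1.0
        marker = int(np.flatnonzero((lam_code[:, j] == FIXED) & (lam_fixed[:, j] != 0))[0])
        tau_code[marker] = FIXED
    phi_code = np.full((r, r), FREE)
    spec = ModelSpec(
        p=p, r=r, G=G, lam_code=lam_code, lam_fixed=lam_fixed,
        phi_code=phi_code, phi_fixed=np.zeros((r, r)),
        mean_structure=True, tau_code=tau_code,
        var_names=var_names, factor_names=factors,
    )
    spec.identification_check()
    return spec


# ---------------------------------------------------------------------------
# spec serialization (round-trippable)
# ---------------------------------------------------------------------------

_FIELDS = [
    "lam_code", "lam_fixed", "psi_code", "psi_fixed", "phi_code", "phi_fixed",
    "tau_code", "tau_fixed", "kappa_code", "kappa_fixed",
]


def spec_to_dict(spec: ModelSpec):
    d = {"p": spec.p, "r": spec.r, "G": spec.G, "mean_structure": spec.mean_structure,
         "var_names": list(spec.var_names), "factor_names": list(spec.factor_names)}
    for f in _FIELDS:
        v = getattr(spec, f)
        d[f] = None if v is None else np.asarray(v).tolist()
    return d


def spec_from_dict(d):
    kwargs = {k: d[k] for k in ("p", "r", "G", "mean_structure")}
    kwargs["var_names"] = d.get("var_names")
    kwargs["factor_names"] = d.get("factor_names")
    for f in _FIELDS:
        v = d.get(f)
        kwargs[f] = None if v is None else np.asarray(v)
    return ModelSpec(**kwargs)


# ---------------------------------------------------------------------------
# data and config reading
# ---------------------------------------------------------------------------

def read_table(path, group_col=None):
    """Read a CSV data table; returns (X DataFrame, group labels or None)."""
    df = pd.read_csv(path)
    groups = None
    if group_col is not None:
        if group_col not in df.columns:
            raise KeyError(f"group column {group_col!r} not found in {path}")
        groups = df[group_col].to_numpy()
        df = df.drop(columns=[group_col])
    return df, groups


def read_sufficient(cov_paths, Ns, mean_paths=None):
    """Build a :class:`DataSummary` from delimited sufficient statistics.

    ``cov_paths`` is one path (or a per-group list) to a whitespace- or
    comma-delimited covariance matrix; ``Ns`` the matching sample size(s);
    ``mean_paths`` optional per-group mean vectors (activating the mean
    structure).
    """
    if isinstance(cov_paths, (str, bytes)):
        cov_paths = [cov_paths]
    Ns = np.atleast_1d(Ns)
    covs = [np.loadtxt(p, delimiter="," if str(p).endswith(".csv") else None) for p in cov_paths]
    xbar = None
    if mean_paths is not None:
        if isinstance(mean_paths, (str, bytes)):
            mean_paths = [mean_paths]
        xbar = np.stack(
            [np.loadtxt(p, delimiter="," if str(p).endswith(".csv") else None) for p in mean_paths]
        )
    return DataSummary(Ns=Ns, S=np.stack(covs), xbar=xbar)


_CONFIG_KEYS = {"penalty", "eta", "a", "gamma", "c_bar", "weights", "information", "vcov", "n_factors", "model"}


def read_config(path):
    """Read a YAML penalty/estimation configuration, validating key names."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    unknown = set(cfg) - _CONFIG_KEYS
    if unknown:
        raise KeyError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    return cfg
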