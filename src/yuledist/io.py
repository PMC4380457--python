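"""File formats: Newick trees, distance matrices (TSV / PHYLIP-square),
histogram TSVs, fit reports (JSON) and deterministic test fixtures.

Branch lengths are interpreted as time.  Unit conversion (e.g. the bird data
are in units of 10^8 yr) is done with a single multiplicative ``time_scale``
applied on read/write only; everything internal is dimensionless.
"""
from __future__ import annotations

import json
import math
import warnings
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Union

import numpy as np

from . import __version__
from .errors import FormatError, ParameterError
from .inference import BoundClaim, FitResult, implied_sigma, sigma_upper_bound
from .params import NMIN1, PAIRWISE, PairStatisticKind, YuleParams
from .simulate import SimulationConfig, simulate_tree
from .stats import DistanceHistogram, DistanceMatrix

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_trees",
    "write_histogram",
    "read_histogram",
    "write_report",
    "make_fixtures",
    "write_fixtures",
]

_FLOAT = "%.17g"  # full double precision, locale-independent


# ----------------------------------------------------------------------------
# distance matrices
# ----------------------------------------------------------------------------

def read_matrix(path, dialect: str = "tsv", time_scale: float = 1.0,
                T: Optional[float] = None) -> DistanceMatrix:
    """Read a square labelled distance matrix.

    ``tsv``: header row of labels (leading empty cell), one labelled row per
    leaf.  ``phylip``: leaf count on the first line, then label + values per
    row (square dialect).  Distances are divided by ``time_scale``.
    """
    lines = [ln.rstrip("\n") for ln in Path(path).read_text().splitlines()
             if ln.strip() != ""]
    if not lines:
        raise FormatError(f"{path}: empty matrix file")
    if dialect == "tsv":
        header = lines[0].split("\t")
        labels = [h for h in header[1:] if h != ""]
        rows = lines[1:]
    elif dialect == "phylip":
        try:
            n = int(lines[0].split()[0])
        except ValueError:
            raise FormatError(f"{path}: PHYLIP matrix must start with the leaf count")
        labels = None
        rows = lines[1:]
        if len(rows) != n:
            raise FormatError(f"{path}: expected {n} rows, found {len(rows)}")
    else:
        raise ParameterError(f"unknown matrix dialect {dialect!r}")
    row_labels, values = [], []
    for i, row in enumerate(rows):
        parts = row.split("\t") if dialect == "tsv" else row.split()
        if len(parts) < 2:
            raise FormatError(f"{path}: row {i + 1} has no values")
        row_labels.append(parts[0])
        try:
            values.append([float(x) for x in parts[1:]])
        except ValueError as e:
            raise FormatError(f"{path}: row {i + 1}: {e}")
    if labels is None:
        labels = row_labels
    lens = {len(v) for v in values}
    if len(lens) != 1 or lens.pop() != len(labels):
        raise FormatError(f"{path}: ragged rows or row/column count mismatch")
    if dialect == "tsv" and row_labels != list(labels):
        raise FormatError(f"{path}: row labels do not match column labels")
    v = np.asarray(values, float) / time_scale
    return DistanceMatrix(tuple(labels), v, T=T)


def write_matrix(matrix: DistanceMatrix, path, dialect: str = "tsv",
                 time_scale: float = 1.0) -> None:
    v = matrix.values * time_scale
    with open(path, "w") as fh:
        if dialect == "tsv":
            fh.write("\t" + "\t".join(matrix.labels) + "\n")
            for lab, row in zip(matrix.labels, v):
                fh.write(lab + "\t" + "\t".join(_FLOAT % x for x in row) + "\n")
        elif dialect == "phylip":
            fh.write(f"{matrix.n}\n")
            for lab, row in zip(matrix.labels, v):
                fh.write(lab + " " + " ".join(_FLOAT % x for x in row) + "\n")
        else:
            raise ParameterError(f"unknown matrix dialect {dialect!r}")


# ----------------------------------------------------------------------------
# Newick trees
# ----------------------------------------------------------------------------

def read_trees(path, time_scale: float = 1.0,
               ultrametric_tol: float = 1e-6) -> List[DistanceMatrix]:
    """Read one or more Newick trees into cophenetic distance matrices.

    The distance between two leaves is the sum of branch lengths on the path
    (equal to 2 (T - t_MRCA) on an ultrametric tree); the height T is the
    maximal root-to-leaf path.  Non-ultrametric trees are accepted with a
    warning; missing or negative branch lengths are format errors.
    """
    import dendropy

    try:
        trees = dendropy.TreeList.get(path=str(path), schema="newick")
    except Exception as e:  # dendropy raises several parse error types
        line = getattr(e, "line_num", None)
        where = f" (line {line})" if line else ""
        raise FormatError(f"{path}: unparseable Newick{where}: {e}")
    if not trees:
        raise FormatError(f"{path}: no trees found")
    out = []
    for idx, tree in enumerate(trees):
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                raise FormatError(f"{path}: tree {idx + 1} has a branch without length")
            if edge.length < 0:
                raise FormatError(f"{path}: tree {idx + 1} has a negative branch length")
        leaves = [lf for lf in tree.leaf_node_iter()]
        labels = [lf.taxon.label if lf.taxon else f"leaf{i}"
                  for i, lf in enumerate(leaves)]
        tree.calc_node_root_distances()
        depths = np.array([lf.root_distance for lf in leaves], float)
        T = float(depths.max()) if len(depths) else 0.0
        if len(depths) > 1 and T > 0 and (T - depths.min()) > ultrametric_tol * T:
            warnings.warn(
                f"{path}: tree {idx + 1} is not ultrametric "
                f"(leaf depths span [{depths.min():.6g}, {T:.6g}]); "
                f"distances kept as path lengths", stacklevel=2)
        pdm = tree.phylogenetic_distance_matrix()
        m = len(leaves)
        v = np.zeros((m, m))
        for a in range(m):
            for b in range(a + 1, m):
                d = pdm.patristic_distance(leaves[a].taxon, leaves[b].taxon)
                v[a, b] = v[b, a] = d
        out.append(DistanceMatrix(tuple(labels), v / time_scale, T=T / time_scale))
    return out


# ----------------------------------------------------------------------------
# histograms
# ----------------------------------------------------------------------------

def write_histogram(hist: DistanceHistogram, path,
                    params: Optional[YuleParams] = None,
                    seed: Optional[int] = None,
                    time_scale: float = 1.0,
                    extra: Optional[Dict[str, str]] = None) -> None:
    """Histogram TSV with a commented header carrying provenance.

    Columns: bin_left, bin_right, count, density and -- when ensemble
    moments are present -- conditional_mean_count, trees_nonzero, sumsq.
    """
    meta = {"version": __version__, "n_trees": hist.n_trees}
    if hist.kind is not None:
        meta["kind"] = str(hist.kind)
    if params is not None:
        meta.update(lam=params.lam, mu=params.mu, sigma=params.sigma, T=params.T)
    if seed is not None:
        meta["seed"] = seed
    if time_scale != 1.0:
        meta["time_scale"] = time_scale
    if extra:
        meta.update(extra)
    ens = hist.sumsq is not None and hist.nonzero_trees is not None
    cols = ["bin_left", "bin_right", "count", "density"]
    if ens:
        cols += ["conditional_mean_count", "trees_nonzero", "sumsq"]
    with open(path, "w") as fh:
        fh.write("# yuledist histogram\n")
        for k, v in meta.items():
            fh.write(f"# {k}={v}\n")
        fh.write("# " + "\t".join(cols) + "\n")
        dens = hist.density / time_scale
        for i in range(hist.n_bins):
            row = [_FLOAT % (hist.edges[i] * time_scale),
                   _FLOAT % (hist.edges[i + 1] * time_scale),
                   _FLOAT % hist.counts[i],
                   _FLOAT % dens[i]]
            if ens:
                nz = int(hist.nonzero_trees[i])
                cm = hist.counts[i] / nz if nz else math.nan
                row += [_FLOAT % cm, str(nz), _FLOAT % hist.sumsq[i]]
            fh.write("\t".join(row) + "\n")


def read_histogram(path, time_scale: float = 1.0) -> DistanceHistogram:
    meta: Dict[str, str] = {}
    lefts, rights, counts, nz, sq = [], [], [], [], []
    for ln in Path(path).read_text().splitlines():
        if not ln.strip():
            continue
        if ln.startswith("#"):
            body = ln[1:].strip()
            if "=" in body and "\t" not in body:
                k, _, v = body.partition("=")
                meta[k.strip()] = v.strip()
            continue
        parts = ln.split("\t")
        if len(parts) not in (4, 7):
            raise FormatError(f"{path}: malformed histogram row: {ln!r}")
        try:
            lefts.append(float(parts[0]))
            rights.append(float(parts[1]))
            counts.append(float(parts[2]))
            if len(parts) == 7:
                nz.append(int(parts[5]))
                sq.append(float(parts[6]))
        except ValueError as e:
            raise FormatError(f"{path}: {e}")
    if not lefts:
        raise FormatError(f"{path}: histogram file has no bins")
    edges = np.array(lefts + [rights[-1]]) / time_scale
    kind = PairStatisticKind.parse(meta["kind"]) if "kind" in meta else None
    return DistanceHistogram(
        edges=edges, counts=np.array(counts),
        n_trees=int(meta.get("n_trees", 1)), kind=kind,
        sumsq=np.array(sq) if sq else None,
        nonzero_trees=np.array(nz) if nz else None)


# ----------------------------------------------------------------------------
# fit reports
# ----------------------------------------------------------------------------

def report_dict(fit: FitResult,
                mu_over_lambda: Sequence[float] = (0.0, 0.2, 0.4, 0.6, 0.8),
                claims: Optional[Iterable[BoundClaim]] = None,
                seed: Optional[int] = None,
                time_scale: float = 1.0) -> dict:
    """Assemble the JSON-serializable fit report (rates in user time units)."""
    def _num(x):
        return None if x is None or (isinstance(x, float) and math.isnan(x)) else x

    rep = {
        "r": _num(fit.r / time_scale if math.isfinite(fit.r) else fit.r),
        "q": _num(fit.q / time_scale if math.isfinite(fit.q) else fit.q),
        "A": _num(fit.A),
        "se_r": _num(fit.se_r / time_scale if math.isfinite(fit.se_r) else None),
        "se_q": _num(fit.se_q / time_scale if math.isfinite(fit.se_q) else None),
        "se_A": _num(fit.se_A),
        "converged": bool(fit.converged),
        "n_iterations": fit.n_iter,
        "n_points": fit.n_points,
        "rms_weighted_residual": _num(fit.rms),
        "window": list(fit.window) if fit.window else None,
        "time_scale": time_scale,
    }
    if fit.converged and fit.r > 0 and fit.q > 0:
        rep["sigma_upper_bound"] = sigma_upper_bound(fit)
        rep["implied_sigma"] = {f"{x:g}": implied_sigma(fit, x) for x in mu_over_lambda}
    else:
        rep["sigma_upper_bound"] = None
        rep["implied_sigma"] = {}
    rep["maximum_claims"] = [
        {"kind": str(c.kind), "sigma_bound": c.bound, "t_peak": c.t_peak,
         "caveat": c.caveat} for c in (claims or [])]
    if seed is not None:
        rep["seed"] = seed
    return rep


def write_report(fit: FitResult, path, **kwargs) -> dict:
    rep = report_dict(fit, **kwargs)
    with open(path, "w") as fh:
        json.dump(rep, fh, indent=2)
        fh.write("\n")
    return rep


# ----------------------------------------------------------------------------
# fixtures
# ----------------------------------------------------------------------------

def make_fixtures(seed: int = 0) -> dict:
    """Deterministic small inputs for tests and demos.

    * ``toy_matrix`` -- the 5-leaf example matrix (two cherries (1,3), (7,8));
    * ``matrix19`` -- a simulated tree with exactly 19 observed leaves
      (171 pairs) at (lam=11, mu=5, sigma=0.01, T=1);
    * ``newicks`` -- ten simulated observed-leaf trees at
      (lam=6, mu=3, sigma=0.1, T=1);
    * ``exact_histograms`` -- noiseless curve samples (r=4, q=0.6,
      A=0.1 e^4) for fitter tests.
    """
    labels = ("1", "3", "5", "7", "8")
    v = np.full((5, 5), 2.0)
    np.fill_diagonal(v, 0.0)
    idx = {lab: i for i, lab in enumerate(labels)}

    def put(a, b, d):
        v[idx[a], idx[b]] = v[idx[b], idx[a]] = d

    put("1", "3", 0.3)
    put("7", "8", 0.2)
    put("5", "7", 0.6)
    put("5", "8", 0.6)
    toy = DistanceMatrix(labels, v, T=1.0)

    cfg = SimulationConfig(YuleParams(11.0, 5.0, 0.01, 1.0), n_trees=100000, seed=seed)
    matrix19 = None
    for i in range(cfg.n_trees):
        tree = simulate_tree(cfg, i)
        if tree.n_observed == 19:
            matrix19 = tree.distance_matrix()
            break
    if matrix19 is None:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("no 19-leaf tree found in the scanned ensemble")

    cfg2 = SimulationConfig(YuleParams(6.0, 3.0, 0.1, 1.0), n_trees=100000,
                            seed=seed + 1)
    newicks = []
    i = 0
    while len(newicks) < 10:
        tree = simulate_tree(cfg2, i)
        i += 1
        if tree.n_observed >= 2:
            newicks.append(tree.to_newick())

    from .inference import model_density
    r, q, A = 4.0, 0.6, 0.1 * math.exp(4.0)
    edges = np.linspace(0.0, 2.0, 101)
    centers = 0.5 * (edges[:-1] + edges[1:])
    exact = {}
    for kind in (PAIRWISE, NMIN1):
        dens = model_density(kind, r, q, A, centers)
        exact[str(kind)] = DistanceHistogram(
            edges=edges, counts=np.asarray(dens) * np.diff(edges),
            n_trees=1, kind=kind)
    return {"toy_matrix": toy, "matrix19": matrix19, "newicks": newicks,
            "exact_histograms": exact,
            "exact_combinations": {"r": r, "q": q, "A": A}}


def write_fixtures(seed: int, outdir) -> List[str]:
    """Write the fixture bundle to ``outdir``; returns the file names."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fx = make_fixtures(seed)
    written = []
    write_matrix(fx["toy_matrix"], outdir / "toy_matrix.tsv")
    written.append("toy_matrix.tsv")
    write_matrix(fx["matrix19"], outdir / "leaves19.tsv")
    written.append("leaves19.tsv")
    (outdir / "trees10.nwk").write_text("\n".join(fx["newicks"]) + "\n")
    written.append("trees10.nwk")
    for name, hist in fx["exact_histograms"].items():
        fname = f"exact_{name}.tsv"
        write_histogram(hist, outdir / fname, seed=seed)
        written.append(fname)
    return written
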