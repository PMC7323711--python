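"""Readers and writers: NEXUS character matrices (via dendropy), NEXUS
tree logs, TSV fossil-site tables and parameter traces, and the flat
key = value analysis configuration file.

All readers reject malformed input rather than silently coercing it, and
write-then-read round-trips are the identity at the stated precisions.
"""
from __future__ import annotations

import dataclasses
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .datamodel import (
    MISSING, CharacterMatrix, DatedTree, FossilSite, StratSequence,
)
from .models import PriorConfig

# ----------------------------------------------------------------------
# Analysis configuration
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class AnalysisConfig:
    """One analysis: file paths, chain settings and prior hyperparameters.

    Defaults are the package's standard analysis settings: Mkv with
    four discrete-gamma categories, uncorrelated lognormal clock with an
    offset-exponential clock-rate prior (mean 0.003, offset 0.0016),
    exponential(1) clock-sd prior, uniform(0, 10) shape prior, lognormal
    (mean in real space 0.14, sdlog 0.9) birth prior, exponential death
    (mean 0.1) and sampling (mean 0.03) priors, 10% summary-time burn-in.
    """

    matrix: str | None = None
    site_table: str | None = None
    output_prefix: str | None = None
    chain_length: int = 100_000
    log_interval: int = 100
    burnin: float = 0.10
    seed: int = 1
    prior_only: bool = False
    link_site_ages: bool = True
    log_trees: bool = True
    gamma_ncat: int = 4
    conditioning: str = "variable"
    clock_rate_prior_mean: float = 0.003
    clock_rate_prior_offset: float = 0.0016
    clock_sd_prior_mean: float = 1.0
    shape_prior_max: float = 10.0
    birth_prior_mean_real: float = 0.14
    birth_prior_sdlog: float = 0.9
    death_prior_mean: float = 0.1
    sampling_prior_mean: float = 0.03
    operator_weights: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.chain_length < 0:
            raise ValueError("chain_length must be >= 0")
        if not 0 <= self.burnin < 1:
            raise ValueError("burn-in fraction must be in [0, 1)")
        if self.log_interval < 1:
            raise ValueError("log_interval must be >= 1")
        if self.conditioning not in ("none", "variable"):
            raise ValueError("conditioning must be 'none' or 'variable'")

    def priors(self) -> PriorConfig:
        return PriorConfig(
            clock_rate_mean=self.clock_rate_prior_mean,
            clock_rate_offset=self.clock_rate_prior_offset,
            clock_sd_mean=self.clock_sd_prior_mean,
            shape_max=self.shape_prior_max,
            birth_mean_real=self.birth_prior_mean_real,
            birth_sdlog=self.birth_prior_sdlog,
            death_mean=self.death_prior_mean,
            sampling_mean=self.sampling_prior_mean,
        )

    def replace(self, **kw) -> "AnalysisConfig":
        return dataclasses.replace(self, **kw)


_CONFIG_FIELDS = {f.name: f for f in dataclasses.fields(AnalysisConfig)}


def read_config(path) -> AnalysisConfig:
    """Parse a flat ``key = value`` config file (# starts a comment)."""
    kw: dict = {}
    weights: dict[str, float] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, val = (s.strip() for s in line.split("=", 1))
        if key.startswith("weight_"):
            weights[key[len("weight_"):]] = float(val)
            continue
        if key not in _CONFIG_FIELDS or key == "operator_weights":
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        ftype = _CONFIG_FIELDS[key].type
        if "bool" in str(ftype):
            if val.lower() not in ("true", "false"):
                raise ValueError(f"{path}:{lineno}: {key} must be true/false")
            kw[key] = val.lower() == "true"
        elif "int" in str(ftype):
            kw[key] = int(val)
        elif "float" in str(ftype):
            kw[key] = float(val)
        else:
            kw[key] = val
    if weights:
        kw["operator_weights"] = weights
    return AnalysisConfig(**kw)


def write_config(config: AnalysisConfig, path) -> None:
    lines = []
    for f in dataclasses.fields(config):
        val = getattr(config, f.name)
        if f.name == "operator_weights":
            if val:
                for k, v in sorted(val.items()):
                    lines.append(f"weight_{k} = {v}")
            continue
        if val is None:
            continue
        if isinstance(val, bool):
            val = "true" if val else "false"
        lines.append(f"{f.name} = {val}")
    Path(path).write_text("\n".join(lines) + "\n")


# ----------------------------------------------------------------------
# NEXUS character matrices
# ----------------------------------------------------------------------
def _matrix_block_rows(text: str) -> list[tuple[str, str]]:
    """(taxon, sequence) rows of the MATRIX command, for pre-validation."""
    m = re.search(r"\bmatrix\b(.*?);", text, re.IGNORECASE | re.DOTALL)
    if not m:
        raise ValueError("no MATRIX command found in NEXUS file")
    rows: list[tuple[str, str]] = []
    for raw in m.group(1).splitlines():
        line = re.sub(r"\[.*?\]", "", raw).strip()
        if not line:
            continue
        qm = re.match(r"""^(['"])(.+?)\1\s+(\S.*)$""", line)
        if qm:
            taxon, seq = qm.group(2), qm.group(3)
        else:
            parts = line.split(None, 1)
            if len(parts) != 2:
                raise ValueError(f"malformed matrix row: {line!r}")
            taxon, seq = parts
        rows.append((taxon, seq.replace(" ", "")))
    return rows


def read_nexus_matrix(path) -> CharacterMatrix:
    """Read a non-interleaved NEXUS DATA/CHARACTERS block.

    Symbols map to 0..k-1 in declared SYMBOLS order; both ``?`` and ``-``
    map to :data:`~stratatips.datamodel.MISSING`. Polymorphic codings like
    ``{01}`` are rejected.
    """
    path = Path(path)
    text = path.read_text()
    if re.search(r"\binterleave\b", text, re.IGNORECASE):
        raise ValueError("interleaved NEXUS matrices are not supported")
    sym_m = re.search(r'symbols\s*=\s*"([^"]*)"', text, re.IGNORECASE)
    symbols = sym_m.group(1).replace(" ", "") if sym_m else "0123456789"
    rows = _matrix_block_rows(text)
    seen: set[str] = set()
    for taxon, seq in rows:
        if taxon in seen:
            raise ValueError(f"duplicate taxon label {taxon!r}")
        seen.add(taxon)
        if "{" in seq or "(" in seq:
            raise ValueError(
                f"polymorphic state codings are not supported (taxon {taxon!r})"
            )
        for j, ch in enumerate(seq):
            if ch not in symbols and ch not in "?-":
                raise ValueError(
                    f"undeclared symbol {ch!r} at taxon {taxon!r}, character {j}"
                )
    lengths = {len(seq) for _, seq in rows}
    if len(lengths) > 1:
        raise ValueError("ragged matrix: rows differ in character count")

    try:
        cm = dendropy.StandardCharacterMatrix.get(
            path=str(path), schema="nexus", preserve_underscores=True
        )
    except Exception as err:
        raise ValueError(f"failed to parse NEXUS matrix {path}: {err}") from err
    taxa = [t.label for t in cm.taxon_namespace]
    n_char = lengths.pop()
    data = np.full((len(taxa), n_char), MISSING, dtype=np.int16)
    index = {ch: i for i, ch in enumerate(symbols)}
    for r, taxon in enumerate(cm.taxon_namespace):
        seq = cm[taxon]
        for j, cell in enumerate(seq):
            sym = cell.symbol
            if sym in ("?", "-"):
                continue
            data[r, j] = index[sym]
    return CharacterMatrix(taxa, data)


def write_nexus_matrix(matrix: CharacterMatrix, path) -> None:
    kmax = int(matrix.k.max())
    symbols = "".join(str(i) for i in range(kmax))
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"  DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_char};",
        f'  FORMAT DATATYPE=STANDARD SYMBOLS="{symbols}" MISSING=? GAP=-;',
        "  MATRIX",
    ]
    width = max(len(t) for t in matrix.taxa) + 2
    for i, taxon in enumerate(matrix.taxa):
        seq = "".join(
            "?" if s == MISSING else str(int(s)) for s in matrix.data[i]
        )
        lines.append(f"    {taxon:<{width}}{seq}")
    lines += ["  ;", "END;", ""]
    Path(path).write_text("\n".join(lines))


# ----------------------------------------------------------------------
# Fossil-site tables
# ----------------------------------------------------------------------
_SITE_COLUMNS = ["site", "taxon", "min_age", "max_age", "below", "above"]


def read_site_table(path) -> tuple[list[FossilSite], StratSequence]:
    """TSV with header ``site taxon min_age max_age below above``.

    One FossilSite per distinct site id (initial age at the bound
    midpoint); ``below``/``above`` columns assemble the stratigraphic
    sequence, which is checked for cycles.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in _SITE_COLUMNS[:4] if c not in df.columns]
    if missing_cols:
        raise ValueError(f"site table missing column(s): {', '.join(missing_cols)}")
    sites: dict[str, dict] = {}
    owner: dict[str, str] = {}
    relations: set[tuple[str, str]] = set()
    for _, row in df.iterrows():
        sid = row["site"].strip()
        taxon = row["taxon"].strip()
        if not sid or not taxon:
            raise ValueError("site table has an empty site or taxon field")
        lo, hi = float(row["min_age"]), float(row["max_age"])
        if taxon in owner and owner[taxon] != sid:
            raise ValueError(
                f"taxon {taxon!r} appears in two sites "
                f"({owner[taxon]!r} and {sid!r})"
            )
        owner[taxon] = sid
        rec = sites.setdefault(sid, {"taxa": [], "min": lo, "max": hi})
        if rec["min"] != lo or rec["max"] != hi:
            raise ValueError(f"site {sid!r} has conflicting age bounds")
        if taxon not in rec["taxa"]:
            rec["taxa"].append(taxon)
        for col, as_lower in (("below", True), ("above", False)):
            other = row.get(col, "").strip() if col in df.columns else ""
            if other:
                relations.add((other, sid) if as_lower else (sid, other))
    for lower, upper in relations:
        for end in (lower, upper):
            if end not in sites:
                raise ValueError(
                    f"stratigraphic relation references undeclared site {end!r}"
                )
    seq = StratSequence(sorted(relations))  # raises on cycles
    out = [
        FossilSite(sid, tuple(rec["taxa"]), rec["min"], rec["max"],
                   (rec["min"] + rec["max"]) / 2.0)
        for sid, rec in sites.items()
    ]
    return out, seq


def write_site_table(sites: list[FossilSite], seq: StratSequence, path) -> None:
    below: dict[str, str] = {}
    above: dict[str, str] = {}
    for lower, upper in seq.relations:
        below[upper] = lower
        above[lower] = upper
    rows = []
    for s in sites:
        for taxon in s.taxa:
            rows.append({
                "site": s.site_id, "taxon": taxon,
                "min_age": s.min_age, "max_age": s.max_age,
                "below": below.get(s.site_id, ""),
                "above": above.get(s.site_id, ""),
            })
    pd.DataFrame(rows, columns=_SITE_COLUMNS).to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------------
# Traces
# ----------------------------------------------------------------------
def write_trace(trace, path) -> None:
    """Tab-separated trace, first column the generation, 12 significant
    digits (write-then-read is the identity at that precision)."""
    trace.df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_trace(path):
    from .mcmc import Trace  # local import: io <-> mcmc

    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as err:
        raise ValueError(f"failed to parse trace {path}: {err}") from err
    if df.columns.size == 0 or df.columns[0] != "generation":
        raise ValueError("malformed trace header: first column must be 'generation'")
    if len(df) and not all(pd.api.types.is_numeric_dtype(t) for t in df.dtypes):
        raise ValueError("malformed trace: non-numeric column")
    return Trace.from_dataframe(df)


# ----------------------------------------------------------------------
# Tree logs
# ----------------------------------------------------------------------
def _newick(tree: DatedTree, index: dict[str, int]) -> str:
    def rec(node: int) -> str:
        kids = tree.children.get(node)
        if not kids:
            label = str(index[tree.labels[node]])
        else:
            label = "(" + ",".join(rec(c) for c in kids) + ")"
        if node == tree.root:
            return label
        dur = tree.age[tree.parent[node]] - tree.age[node]
        return f"{label}:{dur:.12g}"

    return rec(tree.root) + ";"


def write_tree_log(trees: list[DatedTree], path) -> None:
    """NEXUS trees block; branch lengths are durations in Ma and each tree
    statement carries its root age so absolute ages round-trip."""
    trees = list(trees)
    taxa: list[str] = sorted(trees[0].taxa()) if trees else []
    for t in trees:
        if sorted(t.taxa()) != taxa:
            raise ValueError("all logged trees must share one taxon set")
    index = {lab: i + 1 for i, lab in enumerate(taxa)}
    lines = ["#NEXUS", "BEGIN TREES;"]
    if taxa:
        lines.append("  Translate")
        for lab, i in index.items():
            sep = "" if i == len(taxa) else ","
            lines.append(f"    {i} {lab}{sep}")
        lines.append("  ;")
    for n, t in enumerate(trees):
        root_age = t.age[t.root]
        lines.append(
            f"  tree STATE_{n} [&root_age={root_age:.12g}] = [&R] {_newick(t, index)}"
        )
    lines += ["END;", ""]
    Path(path).write_text("\n".join(lines))


def read_tree_log(path) -> list[DatedTree]:
    """Re-read a tree log; node ages are root_age minus root-to-node depth
    (falling back to youngest-tip-at-zero if the root age comment is
    absent)."""
    text = Path(path).read_text()
    root_ages = [float(x) for x in re.findall(r"\[&root_age=([^\]]+)\]", text)]
    tl = dendropy.TreeList.get(
        data=text, schema="nexus", preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    out: list[DatedTree] = []
    for i, dtree in enumerate(tl):
        parent: dict[int, int] = {}
        children: dict[int, tuple[int, ...]] = {}
        depth: dict[int, float] = {}
        labels: dict[int, str] = {}
        ids: dict = {}
        for nd in dtree.preorder_node_iter():
            ids[nd] = len(ids)
            j = ids[nd]
            if nd.parent_node is None:
                depth[j] = 0.0
            else:
                p = ids[nd.parent_node]
                parent[j] = p
                depth[j] = depth[p] + (nd.edge.length or 0.0)
            kids = nd.child_nodes()
            if kids:
                children[j] = tuple(ids[c] for c in kids) if all(
                    c in ids for c in kids
                ) else ()
            else:
                labels[j] = nd.taxon.label
        # second pass for children ids (preorder assigns children later)
        for nd, j in ids.items():
            kids = nd.child_nodes()
            if kids:
                children[j] = tuple(ids[c] for c in kids)
        if i < len(root_ages):
            root_age = root_ages[i]
        else:
            root_age = max(depth.values())
        age = {j: root_age - d for j, d in depth.items()}
        out.append(DatedTree(parent, children, age, labels, ids[dtree.seed_node]))
    return out


# ----------------------------------------------------------------------
def load_analysis(config: AnalysisConfig, base_dir=None):
    """Load the matrix and site table named by a config into AnalysisData."""
    from .mcmc import AnalysisData

    base = Path(base_dir) if base_dir is not None else Path(".")
    matrix = None
    if config.matrix:
        matrix = read_nexus_matrix(base / config.matrix)
    if not config.site_table:
        raise ValueError("config names no site table")
    sites, seq = read_site_table(base / config.site_table)
    if matrix is not None:
        known = set(matrix.taxa)
        for s in sites:
            for taxon in s.taxa:
                if taxon not in known:
                    warnings.warn(
                        f"site {s.site_id} taxon {taxon} absent from matrix",
                        stacklevel=2,
                    )
    return AnalysisData(matrix=matrix, sites=sites, seq=seq)
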