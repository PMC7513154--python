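"""Reading and writing networks and datasets.

Two network dialects are supported:

* a subset of the BIF (Bayesian Interchange Format) text format covering
  ``network``, ``variable`` and ``probability`` blocks (files ending in
  ``.bif``);
* a plain two-file format: a CPT file that fully defines variables, arities,
  parents and tables, plus a sibling ``.arcs`` file listing
  ``parent<TAB>child`` lines (written for human inspection; the CPT file is
  authoritative on read).

Datasets are CSV: a header row of variable names, then integer state codes.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import (DiscreteBayesNet, DiscreteDataset, DirectedAcyclicStructure,
                    Variable)

__all__ = ["read_network", "write_network", "read_dataset", "write_dataset",
           "ParseError"]


class ParseError(ValueError):
    """Malformed network file; the message names the offending line."""


def read_network(path: str | Path) -> DiscreteBayesNet:
    path = Path(path)
    if path.suffix.lower() == ".bif":
        return _read_bif(path)
    return _read_plain(path)


def write_network(bn: DiscreteBayesNet, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".bif":
        _write_bif(bn, path)
    else:
        _write_plain(bn, path)


# ---------------------------------------------------------------------------
# BIF subset
# ---------------------------------------------------------------------------

_VAR_RE = re.compile(r"variable\s+(\S+)\s*\{")
_TYPE_RE = re.compile(r"type\s+discrete\s*\[\s*(\d+)\s*\]\s*\{([^}]*)\}\s*;")
_PROB_RE = re.compile(r"probability\s*\(\s*([^)|]+?)\s*(?:\|\s*([^)]+?)\s*)?\)\s*\{")


def _read_bif(path: Path) -> DiscreteBayesNet:
    lines = path.read_text().splitlines()
    variables: list[Variable] = []
    states: dict[str, list[str]] = {}
    cpt_blocks: list[tuple[str, list[str], dict, int]] = []

    i = 0
    n_lines = len(lines)

    def err(lineno: int, msg: str) -> ParseError:
        return ParseError(f"{path.name}:{lineno + 1}: {msg}")

    while i < n_lines:
        line = lines[i].strip()
        if not line or line.startswith("//") or line.startswith("network"):
            # skip the network block body if it spans lines
            if line.startswith("network") and "}" not in line:
                while i < n_lines and "}" not in lines[i]:
                    i += 1
            i += 1
            continue
        m = _VAR_RE.match(line)
        if m:
            name = m.group(1)
            i += 1
            arity = None
            while i < n_lines and lines[i].strip() != "}":
                tm = _TYPE_RE.search(lines[i])
                if tm:
                    arity = int(tm.group(1))
                    states[name] = [s.strip() for s in tm.group(2).split(",") if s.strip()]
                    if len(states[name]) != arity:
                        raise err(i, f"variable {name!r}: {len(states[name])} state names "
                                     f"declared but arity is {arity}")
                i += 1
            if arity is None:
                raise err(i if i < n_lines else n_lines - 1,
                          f"variable {name!r} has no discrete type declaration")
            variables.append(Variable(name, arity))
            i += 1
            continue
        m = _PROB_RE.match(line)
        if m:
            child = m.group(1).strip()
            parents = ([p.strip() for p in m.group(2).split(",")] if m.group(2) else [])
            start = i
            body: dict = {}
            i += 1
            while i < n_lines and "}" not in lines[i]:
                row = lines[i].strip().rstrip(";").strip()
                if not row:
                    i += 1
                    continue
                if row.startswith("table"):
                    body["table"] = _parse_floats(row[len("table"):], i, path)
                elif row.startswith("("):
                    close = row.index(")")
                    key = tuple(s.strip() for s in row[1:close].split(","))
                    body[key] = _parse_floats(row[close + 1:], i, path)
                else:
                    raise err(i, f"unrecognized probability entry: {row!r}")
                i += 1
            cpt_blocks.append((child, parents, body, start))
            i += 1
            continue
        raise err(i, f"unrecognized statement: {line!r}")

    if not variables:
        raise ParseError(f"{path.name}: no variable blocks found")

    name_to_var = {v.name: v for v in variables}
    arcs = []
    for child, parents, _, start in cpt_blocks:
        for p in parents:
            if p not in name_to_var:
                raise ParseError(f"{path.name}:{start + 1}: unknown parent {p!r}")
            arcs.append((p, child))
    structure = DirectedAcyclicStructure(variables, arcs)

    cpts: dict[str, np.ndarray] = {}
    for child, file_parents, body, start in cpt_blocks:
        r = name_to_var[child].arity
        # canonical parent order (variable order) may differ from file order
        canon_parents = structure.parents(child)
        p_arities = [name_to_var[p].arity for p in canon_parents]
        q = int(np.prod(p_arities)) if p_arities else 1
        table = np.full((q, r), np.nan)
        if not file_parents:
            vec = body.get("table")
            if vec is None or len(vec) != r:
                raise ParseError(f"{path.name}:{start + 1}: root CPT for {child!r} "
                                 f"must be a 'table' line with {r} values")
            table[0] = vec
        else:
            for key, vec in body.items():
                if key == "table":
                    raise ParseError(f"{path.name}:{start + 1}: 'table' not allowed for "
                                     f"conditional CPT of {child!r}")
                if len(key) != len(file_parents):
                    raise ParseError(f"{path.name}:{start + 1}: configuration {key} does "
                                     f"not match parent list {file_parents}")
                if len(vec) != r:
                    raise ParseError(f"{path.name}:{start + 1}: row for {key} has "
                                     f"{len(vec)} values, expected {r}")
                cfg = {}
                for p, sname in zip(file_parents, key):
                    if sname not in states[p]:
                        raise ParseError(f"{path.name}:{start + 1}: unknown state "
                                         f"{sname!r} of parent {p!r}")
                    cfg[p] = states[p].index(sname)
                row = 0
                for p in canon_parents:
                    row = row * name_to_var[p].arity + cfg[p]
                table[row] = vec
        if np.isnan(table).any():
            raise ParseError(f"{path.name}:{start + 1}: CPT for {child!r} is missing "
                             f"parent configurations")
        sums = table.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9, rtol=0.0):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise ParseError(f"{path.name}:{start + 1}: CPT row for {child!r} sums to "
                             f"{sums[bad]:.12g}, expected 1")
        cpts[child] = table
    return DiscreteBayesNet(structure, cpts)


def _parse_floats(text: str, lineno: int, path: Path) -> list[float]:
    try:
        return [float(tok) for tok in text.replace(",", " ").split()]
    except ValueError as exc:
        raise ParseError(f"{path.name}:{lineno + 1}: bad probability value ({exc})") from None


def _state_names(v: Variable) -> list[str]:
    return [f"s{k}" for k in range(v.arity)]


def _write_bif(bn: DiscreteBayesNet, path: Path) -> None:
    out = ["network unknown {", "}"]
    for v in bn.structure.variables:
        names = ", ".join(_state_names(v))
        out.append(f"variable {v.name} {{")
        out.append(f"  type discrete [ {v.arity} ] {{ {names} }};")
        out.append("}")
    for v in bn.structure.variables:
        parents = bn.structure.parents(v.name)
        table = bn.cpts[v.name]
        if not parents:
            out.append(f"probability ( {v.name} ) {{")
            out.append("  table " + ", ".join(f"{p:.17g}" for p in table[0]) + ";")
        else:
            out.append(f"probability ( {v.name} | {', '.join(parents)} ) {{")
            p_arities = [bn.structure.arity(p) for p in parents]
            for row in range(table.shape[0]):
                cfg, rem = [], row
                for r in reversed(p_arities):
                    cfg.append(rem % r)
                    rem //= r
                cfg = cfg[::-1]
                key = ", ".join(f"s{c}" for c in cfg)
                out.append(f"  ({key}) " + ", ".join(f"{p:.17g}" for p in table[row]) + ";")
        out.append("}")
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# plain two-file format
# ---------------------------------------------------------------------------

def _write_plain(bn: DiscreteBayesNet, path: Path) -> None:
    out = []
    for v in bn.structure.variables:
        parents = bn.structure.parents(v.name)
        head = f"var {v.name} {v.arity}"
        if parents:
            head += " | " + " ".join(parents)
        out.append(head)
        for row in bn.cpts[v.name]:
            out.append(" ".join(f"{p:.17g}" for p in row))
    path.write_text("\n".join(out) + "\n")
    arcs_path = path.with_suffix(path.suffix + ".arcs")
    arc_lines = [f"{p}\t{c}" for p, c in sorted(bn.structure.arcs)]
    arcs_path.write_text("\n".join(arc_lines) + ("\n" if arc_lines else ""))


def _read_plain(path: Path) -> DiscreteBayesNet:
    lines = path.read_text().splitlines()
    variables: list[Variable] = []
    decl: list[tuple[str, list[str], list[list[float]], int]] = []
    current = None
    for lineno, raw in enumerate(lines):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("var "):
            head = line[4:]
            if "|" in head:
                left, right = head.split("|", 1)
                parents = right.split()
            else:
                left, parents = head, []
            toks = left.split()
            if len(toks) != 2:
                raise ParseError(f"{path.name}:{lineno + 1}: expected 'var NAME ARITY'")
            name, arity_s = toks
            try:
                arity = int(arity_s)
            except ValueError:
                raise ParseError(f"{path.name}:{lineno + 1}: bad arity {arity_s!r}") from None
            variables.append(Variable(name, arity))
            current = (name, parents, [], lineno)
            decl.append(current)
        else:
            if current is None:
                raise ParseError(f"{path.name}:{lineno + 1}: probability row before "
                                 f"any 'var' header")
            current[2].append(_parse_floats(line, lineno, path))
    if not variables:
        raise ParseError(f"{path.name}: no 'var' declarations found")
    arcs = [(p, name) for name, parents, _, _ in decl for p in parents]
    structure = DirectedAcyclicStructure(variables, arcs)
    cpts: dict[str, np.ndarray] = {}
    for name, parents, rows, lineno in decl:
        q = int(np.prod([structure.arity(p) for p in structure.parents(name)])) \
            if structure.parents(name) else 1
        table = np.asarray(rows, dtype=float)
        if table.shape != (q, structure.arity(name)):
            raise ParseError(f"{path.name}:{lineno + 1}: CPT for {name!r} must have "
                             f"{q} rows of {structure.arity(name)} values, got {table.shape}")
        sums = table.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9, rtol=0.0):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise ParseError(f"{path.name}:{lineno + 1}: CPT row {bad} of {name!r} sums "
                             f"to {sums[bad]:.12g}, expected 1")
        cpts[name] = table
    return DiscreteBayesNet(structure, cpts)


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------

def write_dataset(data: DiscreteDataset, path: str | Path) -> None:
    frame = pd.DataFrame(data.records, columns=[v.name for v in data.variables])
    frame.to_csv(path, index=False)


def read_dataset(path: str | Path,
                 variables: Sequence[Variable] | None = None) -> DiscreteDataset:
    frame = pd.read_csv(path)
    if variables is None:
        variables = [Variable(str(c), max(2, int(frame[c].max()) + 1))
                     for c in frame.columns]
    else:
        missing = [v.name for v in variables if v.name not in frame.columns]
        if missing:
            raise ParseError(f"{Path(path).name}: missing columns {missing}")
        frame = frame[[v.name for v in variables]]
    return DiscreteDataset(tuple(variables), frame.to_numpy(dtype=np.int64))
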