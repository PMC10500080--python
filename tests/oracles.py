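"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — line scans, nested loops, explicit
matrices — and shares no code with the package's own graph/closure logic.
"""

from __future__ import annotations

import re


# ---------------------------------------------------------------------------
# OBO line-scan parsing (oracle for the ontology loader)


def scan_obo(text: str) -> dict[str, dict]:
    """Parse OBO text into raw stanza dicts by plain line scanning."""
    stanzas: dict[str, dict] = {}
    current = None
    in_term = False
    for line in text.splitlines():
        line = line.split(" ! ")[0].strip()
        if line == "[Term]":
            in_term = True
            current = {"alt_id": [], "is_a": [], "relationship": [], "obsolete": False}
            continue
        if line.startswith("["):
            in_term = False
            continue
        if not in_term or not line:
            continue
        if line.startswith("id: "):
            stanzas[line[4:]] = current
        elif line.startswith("alt_id: "):
            current["alt_id"].append(line[8:])
        elif line.startswith("is_a: "):
            current["is_a"].append(line[6:])
        elif line.startswith("relationship: "):
            current["relationship"].append(line[14:])
        elif line.startswith("is_obsolete: true"):
            current["obsolete"] = True
        elif line.startswith("name: "):
            current["name"] = line[6:]
        elif line.startswith("namespace: "):
            current["namespace"] = line[11:]
    return stanzas


def scan_axioms(text: str) -> list[tuple[str, str, int]]:
    """grep-style scan for taxon-constraint relationship lines."""
    out = []
    current_id = None
    for line in text.splitlines():
        line = line.split(" ! ")[0].strip()
        if line.startswith("id: "):
            current_id = line[4:]
        m = re.match(r"relationship: (never_in_taxon|only_in_taxon) NCBITaxon:(\d+)", line)
        if m and current_id:
            rel = "never_in" if m.group(1) == "never_in_taxon" else "only_in"
            out.append((current_id, rel, int(m.group(2))))
    return out


def obo_edges(text: str, propagating=("is_a", "part_of")) -> set[tuple[str, str]]:
    """(child, parent) pairs over propagating relations, from a line scan."""
    edges = set()
    for tid, st in scan_obo(text).items():
        if st["obsolete"]:
            continue
        for parent in st["is_a"]:
            if "is_a" in propagating:
                edges.add((tid, parent))
        for entry in st["relationship"]:
            parts = entry.split()
            if len(parts) == 2 and parts[0] in propagating and parts[1].startswith("GO:"):
                edges.add((tid, parts[1]))
    return edges


# ---------------------------------------------------------------------------
# graph reachability


def brute_descendants(edges: set[tuple[str, str]], node: str) -> set[str]:
    """DFS with a visited set over (child, parent) edges, excluding node."""
    children: dict[str, set[str]] = {}
    for c, p in edges:
        children.setdefault(p, set()).add(c)
    out: set[str] = set()
    stack = [node]
    while stack:
        for child in children.get(stack.pop(), ()):
            if child not in out:
                out.add(child)
                stack.append(child)
    return out


def brute_ancestors_or_self(edges: set[tuple[str, str]], node: str) -> set[str]:
    parents: dict[str, set[str]] = {}
    for c, p in edges:
        parents.setdefault(c, set()).add(p)
    out: set[str] = set()
    stack = [node]
    while stack:
        n = stack.pop()
        if n not in out:
            out.add(n)
            stack.extend(parents.get(n, ()))
    return out


# ---------------------------------------------------------------------------
# taxonomy


def brute_lineage(parent_of: dict[int, int], taxid: int) -> list[int]:
    """Explicit parent-chain walk; root is its own parent."""
    chain = [taxid]
    while parent_of[taxid] != taxid:
        taxid = parent_of[taxid]
        chain.append(taxid)
    return chain


def brute_closest_ref(parent_of: dict[int, int], taxid: int, refset) -> int | None:
    """Filtered lineage, nearest-first."""
    hits = [n for n in brute_lineage(parent_of, taxid) if n in refset]
    return hits[0] if hits else None


# ---------------------------------------------------------------------------
# cumulative frequencies


def brute_cumulative(plan, edges) -> dict[str, int]:
    """Per-annotation ancestor-set union: each line votes once per ancestor."""
    cum: dict[str, int] = {}
    for _taxid, go in plan:
        for anc in brute_ancestors_or_self(edges, go):
            cum[anc] = cum.get(anc, 0) + 1
    return cum


# ---------------------------------------------------------------------------
# sequential-overwrite merge oracle


def overwrite_verdicts(records, parent_of, edges, all_terms, taxid):
    """Three-pass overwrite on the fully expanded (taxon, term) matrix.

    ``records`` are (source, relation, rec_taxon, go) tuples.  Returns the
    prohibited term set for ``taxid``.  Within a tier, permissions apply
    first and prohibitions last (a prohibition wins a same-tier clash).
    """
    lineage = set(brute_lineage(parent_of, taxid))
    verdict: dict[str, bool] = {}
    for tier in ("automatic", "goc", "manual"):
        tier_permit: set[str] = set()
        tier_prohibit: set[str] = set()
        for source, relation, rec_taxon, go in records:
            if source != tier:
                continue
            closure = {t for t in all_terms if go in brute_ancestors_or_self(edges, t)}
            if relation == "never_in":
                if rec_taxon in lineage:
                    tier_prohibit |= closure
            elif relation == "only_in":
                if rec_taxon in lineage:
                    tier_permit |= closure
                else:
                    tier_prohibit |= closure
            elif relation == "allow":
                if rec_taxon in lineage:
                    tier_permit |= closure
        for t in tier_permit:
            verdict[t] = False
        for t in tier_prohibit:
            verdict[t] = True
    return {t for t, prohibited in verdict.items() if prohibited}


# ---------------------------------------------------------------------------
# metric curve


def naive_curve(scores: dict[str, float], truth: set[str], ic: dict[str, float],
                taus) -> dict[str, list]:
    """Per-threshold set recomputation of precision/recall/ru/mi."""
    out = {"precision": [], "recall": [], "wpr": [], "wrc": [], "ru": [], "mi": []}
    ic_T = sum(ic.get(t, 0.0) for t in truth)
    for tau in taus:
        P = {g for g, s in scores.items() if s >= tau}
        inter = P & truth
        out["precision"].append(len(inter) / len(P) if P else None)
        out["recall"].append(len(inter) / len(truth))
        ic_P = sum(ic.get(g, 0.0) for g in P)
        ic_I = sum(ic.get(g, 0.0) for g in inter)
        out["wpr"].append((ic_I / ic_P) if P and ic_P > 0 else None)
        out["wrc"].append(ic_I / ic_T if ic_T > 0 else 0.0)
        out["ru"].append(sum(ic.get(g, 0.0) for g in truth - P))
        out["mi"].append(sum(ic.get(g, 0.0) for g in P - truth))
    return out


def naive_fmax(scores, truth, taus) -> float:
    best = 0.0
    for tau in taus:
        P = {g for g, s in scores.items() if s >= tau}
        if not P:
            continue
        inter = P & truth
        pr = len(inter) / len(P)
        rc = len(inter) / len(truth)
        if pr + rc > 0:
            best = max(best, 2 * pr * rc / (pr + rc))
    return best
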