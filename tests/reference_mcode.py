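"""Independently coded naive reference of the molecular-complex-detection
procedure, built on plain dicts/sets (no graph library, no shared helpers
with the package).  Used as the oracle for k-core numbers, vertex weights
and complex prediction on small graphs."""

from collections import deque


def adjacency(edges):
    adj = {}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    return adj


def ref_core_numbers(nodes, edges):
    """Core numbers by literal repeated peeling for each k."""
    nodes = set(nodes)
    adj = adjacency(edges)
    for n in nodes:
        adj.setdefault(n, set())
    core = {n: 0 for n in nodes}
    k = 1
    while True:
        # peel: repeatedly remove vertices of degree < k
        alive = set(nodes)
        changed = True
        while changed:
            changed = False
            for v in list(alive):
                if len(adj[v] & alive) < k:
                    alive.discard(v)
                    changed = True
        if not alive:
            break
        for v in alive:
            core[v] = k
        k += 1
    return core


def _ref_density(members, adj):
    members = set(members)
    n = len(members)
    if n < 2:
        return 0.0
    e = sum(len(adj.get(v, set()) & members) for v in members) // 2
    return 2.0 * e / (n * (n - 1))


def ref_vertex_weight(nodes, edges, v):
    adj = adjacency(edges)
    for n in nodes:
        adj.setdefault(n, set())
    closed = adj[v] | {v}
    if len(closed) < 2:
        return 0.0
    sub_edges = [(a, b) for a, b in edges if a in closed and b in closed]
    cores = ref_core_numbers(closed, sub_edges)
    k_max = max(cores.values())
    if k_max == 0:
        return 0.0
    highest = {u for u, c in cores.items() if c >= k_max}
    high_adj = adjacency([(a, b) for a, b in sub_edges if a in highest and b in highest])
    return k_max * _ref_density(highest, high_adj)


def ref_predict(nodes, edges, vwp=0.2, degree_cutoff=2, haircut=True, max_depth=100):
    """Naive complex prediction; returns [(frozenset members, seed, score)]
    sorted by score descending then seed."""
    nodes = sorted(set(nodes))
    adj = adjacency(edges)
    for n in nodes:
        adj.setdefault(n, set())
    weights = {
        v: (ref_vertex_weight(nodes, edges, v) if len(adj[v]) >= degree_cutoff else 0.0)
        for v in nodes
    }
    visited = set()
    out = []
    for seed in sorted(nodes, key=lambda v: (-weights[v], v)):
        if seed in visited or weights[seed] <= 0:
            continue
        threshold = weights[seed] * (1 - vwp)
        members = {seed}
        checked = {seed}
        queue = deque([(seed, 0)])
        while queue:
            u, depth = queue.popleft()
            if depth >= max_depth:
                continue
            for w in sorted(adj[u]):
                if w in checked or w in visited:
                    continue
                checked.add(w)
                if weights[w] > threshold:
                    members.add(w)
                    queue.append((w, depth + 1))
        visited |= members
        if haircut:
            while True:
                drop = {u for u in members if len(adj[u] & members) < 2}
                if not drop:
                    break
                members -= drop
        if len(members) < 2:
            continue
        sub_edges = [(a, b) for a, b in edges if a in members and b in members]
        if max(ref_core_numbers(members, sub_edges).values()) < 2:
            continue
        score = _ref_density(members, adj) * len(members)
        out.append((frozenset(members), seed, score))
    out.sort(key=lambda t: (-t[2], t[1]))
    return out
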