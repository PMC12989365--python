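"""Independent brute-force oracles used to cross-check the pipeline.

Deliberately naive: explicit enumeration, no shared code with the package
implementations they verify.
"""

import itertools


def brute_force_frequencies(calls, population):
    """Literal enumeration version of the two-pass frequency estimator.

    Candidate-multiset probabilities are computed by summing the plain
    allele-frequency product over every distinct ordering of the multiset
    (an independent route to multiplicity x product), renormalized within
    each candidate set.
    """
    pop_calls = [c for c in calls if c.population == population]
    unambiguous, ambiguous = [], []
    for c in pop_calls:
        ff = sorted(
            {tuple(sorted((x.first_field() for x in ms), key=str)) for ms in c.candidates}
        )
        (unambiguous if len(ff) == 1 else ambiguous).append(ff)

    counts = {}
    for cands in unambiguous:
        for allele in cands[0]:
            counts[allele] = counts.get(allele, 0) + 1
    total = sum(counts.values())
    g = {allele: v / total for allele, v in counts.items()} if total else {}

    final = {allele: float(v) for allele, v in counts.items()}
    for cands in ambiguous:
        probs = []
        for ms in cands:
            p = 0.0
            for perm in set(itertools.permutations(ms)):
                q = 1.0
                for allele in perm:
                    q *= g.get(allele, 0.0)
                p += q
            probs.append(p)
        s = sum(probs)
        if s == 0.0:
            weights = [1.0 / len(cands)] * len(cands)
        else:
            weights = [p / s for p in probs]
        for ms, w in zip(cands, weights):
            for allele in ms:
                final[allele] = final.get(allele, 0.0) + w

    denom = sum(final.values())
    return {allele: v / denom for allele, v in final.items()}


def random_tree_distances(rng, n_leaves, max_len=10):
    """Random binary tree with integer branch lengths >= 1; returns
    (labels, pairwise path-distance matrix) for oracle-checking NJ."""
    import numpy as np

    # start from leaves, repeatedly join two random subtrees
    forest = [(f"L{i}", None) for i in range(n_leaves)]
    edges = {}  # node -> list of (child, length)
    counter = itertools.count()
    while len(forest) > 1:
        i, j = sorted(rng.choice(len(forest), size=2, replace=False))
        left, right = forest[j], forest[i]
        parent = (f"I{next(counter)}", None)
        edges[parent[0]] = [
            (left[0], int(rng.integers(1, max_len + 1))),
            (right[0], int(rng.integers(1, max_len + 1))),
        ]
        forest = [f for k, f in enumerate(forest) if k not in (i, j)] + [parent]
    # undirected adjacency, then per-leaf BFS for exact path sums
    adj = {}
    for parent, children in edges.items():
        for child, length in children:
            adj.setdefault(parent, []).append((child, length))
            adj.setdefault(child, []).append((parent, length))
    labels = sorted(node for node in adj if node.startswith("L"))
    n = len(labels)
    d = np.zeros((n, n))
    for x, leaf in enumerate(labels):
        dist = {leaf: 0}
        queue = [leaf]
        while queue:
            u = queue.pop()
            for v, length in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + length
                    queue.append(v)
        for y, other in enumerate(labels):
            d[x, y] = dist[other]
    return labels, d
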