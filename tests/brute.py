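"""Independent O(n^2) reference implementations used as test oracles.

Deliberately naive: pairwise distances by explicit loops over numpy
rows, neighbor order by Python's sort on (distance, index), and the
connectivity scores counted edge by edge.  Nothing here touches the
package's kNN index or vectorized score paths.
"""

import numpy as np


def brute_neighbor_order(coords):
    """For each cell, every other cell sorted by (distance, index)."""
    n = coords.shape[0]
    orders = []
    for i in range(n):
        dists = [(float(np.sqrt(((coords[i] - coords[j]) ** 2).sum())), j)
                 for j in range(n) if j != i]
        dists.sort()
        orders.append([j for _, j in dists])
    return orders


def brute_out_edges(orders, i, m):
    """Cell i itself plus its m-1 nearest others."""
    return [i] + orders[i][: m - 1]


def brute_cell_q(coords, cell, k):
    orders = brute_neighbor_order(coords)
    S = brute_out_edges(orders, cell, k)
    total = 0
    for i in S:
        for j in S:
            if j == i or j in orders[i][: k - 1]:
                total += 1
    return total / (k * k)


def brute_cluster_q(coords, members):
    orders = brute_neighbor_order(coords)
    members = list(members)
    n = len(members)
    budget = n if n < 20 else 20
    total = 0
    for i in members:
        for j in members:
            if j == i or j in orders[i][: budget - 1]:
                total += 1
    return total / (n * budget)
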