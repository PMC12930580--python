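"""Independent reference implementations used only to check the package.

Each oracle deliberately uses a different code path (scipy interpolation,
exhaustive enumeration, quadrature, plain gradient descent) from the
implementation it validates.
"""

import itertools

import numpy as np
from scipy.integrate import quad
from scipy.interpolate import interp1d


def equal_arclength_resample(points, n_out):
    """Equal-arclength points on a polyline, via scipy interpolation."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    s /= s[-1]
    return interp1d(s, points, axis=0)(np.linspace(0.0, 1.0, n_out))


def arclength_positions(output, polyline, tol=1e-8):
    """Arclength coordinate of each output point along a polyline.

    Asserts every point actually lies on the polyline (triangle equality on
    some segment) and returns its cumulative arclength position.
    """
    seg = np.linalg.norm(np.diff(polyline, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    positions = []
    for p in output:
        da = np.linalg.norm(p - polyline[:-1], axis=1)
        db = np.linalg.norm(p - polyline[1:], axis=1)
        slack = da + db - seg
        k = int(np.argmin(slack))
        assert slack[k] < tol * max(cum[-1], 1.0), \
            "output point does not lie on the input polyline"
        positions.append(cum[k] + da[k])
    return np.asarray(positions)


def zero_temperature_string(potential, start, end, n_points=100,
                            step=2e-5, n_iter=40000):
    """Dense steepest-descent string: the deterministic minimum-energy path."""
    t = np.linspace(0.0, 1.0, n_points)[:, None]
    s = (1.0 - t) * np.asarray(start) + t * np.asarray(end)
    for _ in range(n_iter):
        s[1:-1] -= step * potential.gradient(s[1:-1])
        s = equal_arclength_resample(s, n_points)
        s[0], s[-1] = start, end
    return s


def brute_force_shortest_paths(graph, weight="weight"):
    """All-pairs shortest distances by exhaustive simple-path enumeration."""
    nodes = sorted(graph.nodes, key=repr)
    dist = {}
    for a, b in itertools.combinations(nodes, 2):
        best = np.inf
        for path in _all_simple_paths(graph, a, b):
            length = sum(graph.edges[u, v][weight]
                         for u, v in zip(path, path[1:]))
            best = min(best, length)
        dist[(a, b)] = best
    return dist


def brute_force_edge_betweenness(graph, weight="weight", tol=1e-12):
    """Edge betweenness by enumerating all co-optimal simple paths,
    splitting each source-target pair equally among them."""
    values = {tuple(sorted(e, key=repr)): 0.0 for e in graph.edges}
    nodes = sorted(graph.nodes, key=repr)
    for a, b in itertools.combinations(nodes, 2):
        paths = list(_all_simple_paths(graph, a, b))
        if not paths:
            continue
        lengths = [sum(graph.edges[u, v][weight]
                       for u, v in zip(p, p[1:])) for p in paths]
        best = min(lengths)
        optimal = [p for p, l in zip(paths, lengths) if l <= best + tol]
        for p in optimal:
            for u, v in zip(p, p[1:]):
                values[tuple(sorted((u, v), key=repr))] += 1.0 / len(optimal)
    return values


def _all_simple_paths(graph, source, target):
    stack = [(source, [source])]
    while stack:
        node, path = stack.pop()
        if node == target:
            yield path
            continue
        for nbr in graph.neighbors(node):
            if nbr not in path:
                stack.append((nbr, path + [nbr]))


def boltzmann_free_energy_difference(potential, kT, split=0.0,
                                     bounds=(-8.0, 8.0)):
    """Exact basin free-energy difference F(x>split) - F(x<split) of a 1-D
    potential by numerical quadrature of the Boltzmann weight."""
    def w(x):
        return np.exp(-potential.energy(np.array([x])) / kT)
    z_hi = quad(w, split, bounds[1])[0]
    z_lo = quad(w, bounds[0], split)[0]
    return -kT * np.log(z_hi / z_lo)


def sample_markov_chain_pairs(transition_matrix, n_pairs, seed):
    """(start, end) state pairs from a trajectory of the given chain."""
    rng = np.random.default_rng(seed)
    t = np.asarray(transition_matrix)
    cdf = np.cumsum(t, axis=1)
    states = np.empty(n_pairs + 1, dtype=int)
    states[0] = 0
    u = rng.random(n_pairs)
    for i in range(n_pairs):
        states[i + 1] = np.searchsorted(cdf[states[i]], u[i])
    return states[:-1], states[1:]
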