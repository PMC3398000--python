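import numpy as np
import pytest

from wildcorridor import GridSpec, LandscapeScenario, generate_landscape


@pytest.fixture
def spec10():
    return GridSpec(n_rows=10, n_cols=10, cell_size=100.0, origin_x=0.0, origin_y=1000.0)


@pytest.fixture(scope="session")
def planted_landscape():
    """Small two-park landscape with a planted low-cost channel."""
    scn = LandscapeScenario(seed=7, extent_km=(20.0, 12.0), planted_channel=True)
    return generate_landscape(scn)


def brute_force_distance(mask: np.ndarray, cell_size: float) -> np.ndarray:
    """O(n^2) oracle: metres from each cell centre to the nearest source centre."""
    src = np.argwhere(mask)
    rows, cols = np.indices(mask.shape)
    out = np.full(mask.shape, np.inf)
    for r, c in src:
        d = np.sqrt((rows - r) ** 2 + (cols - c) ** 2) * cell_size
        out = np.minimum(out, d)
    return out


def graph_dijkstra_acc(values: np.ndarray, sources, cell_size_units=1.0):
    """Independent oracle: shortest paths on an explicitly built 8-neighbour graph."""
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import dijkstra as cs_dijkstra

    n_rows, n_cols = values.shape
    n = n_rows * n_cols
    rows_i, cols_j, w = [], [], []
    for r in range(n_rows):
        for c in range(n_cols):
            for dr, dc in ((-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)):
                nr, nc = r + dr, c + dc
                if 0 <= nr < n_rows and 0 <= nc < n_cols:
                    step = np.sqrt(2.0) if dr and dc else 1.0
                    rows_i.append(r * n_cols + c)
                    cols_j.append(nr * n_cols + nc)
                    w.append(0.5 * (values[r, c] + values[nr, nc]) * step * cell_size_units)
    g = coo_matrix((w, (rows_i, cols_j)), shape=(n, n))
    idx = [r * n_cols + c for r, c in sources]
    dist = cs_dijkstra(g.tocsr(), directed=True, indices=idx)
    return dist.min(axis=0).reshape(values.shape)
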