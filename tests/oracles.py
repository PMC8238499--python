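"""Naive, dense reference implementations used as independent oracles.

Everything here is written directly from the mathematical definitions with
plain loops and O(n^2) scans, deliberately sharing no code with the package
internals.
"""

import numpy as np


def knn_brute(emb, k):
    """All-pairs Euclidean KNN, ties by ascending index, self excluded
    except that exact duplicates of a cell count as neighbors."""
    n = emb.shape[0]
    idx = np.empty((n, k), dtype=int)
    dist = np.empty((n, k))
    for i in range(n):
        d = np.sqrt(((emb - emb[i]) ** 2).sum(axis=1))
        keyed = sorted((dd, j) for j, dd in enumerate(d) if j != i)
        idx[i] = [j for _, j in keyed[:k]]
        dist[i] = [dd for dd, _ in keyed[:k]]
    return idx, dist


def jaccard_all_pairs(indices, include_self=True):
    """Dense Jaccard matrix over neighbor sets by literal set arithmetic."""
    n = indices.shape[0]
    sets = []
    for i in range(n):
        s = set(indices[i].tolist())
        if include_self:
            s.add(i)
        sets.append(s)
    J = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            inter = len(sets[i] & sets[j])
            if inter:
                J[i, j] = inter / len(sets[i] | sets[j])
    return J


def bandwidth_exhaustive(emb, indices, distances, J, n_bw=20, floor=1e-10):
    """Margin-cell bandwidths from a dense Jaccard matrix."""
    n = emb.shape[0]
    sigma = np.empty(n)
    for i in range(n):
        cands = [j for j in range(n) if j != i and J[i, j] > 0]
        if not cands:
            sigma[i] = distances[i, -1]
        else:
            dist = {j: np.linalg.norm(emb[j] - emb[i]) for j in cands}
            cands.sort(key=lambda j: (J[i, j], -dist[j]))
            sel = cands[:n_bw]
            sigma[i] = np.mean([dist[j] for j in sel])
        sigma[i] = max(sigma[i], distances[i, 0] + floor)
    return sigma


def affinity(d, d_first, sigma):
    return np.exp(-max(d - d_first, 0.0) / (sigma - d_first))


def wnn_reference(embs, k=20, n_bw=20, eps=1e-4, candidate_width=None):
    """Full WNN computation for M modalities, straight from the formulas.

    Returns dict with predictions, thetas, ratios, weights, and the top-k
    weighted graph scored over *all* other cells (so candidate truncation in
    the implementation can be validated against exhaustive scoring when
    candidate_width >= n - 1).
    """
    M = len(embs)
    n = embs[0].shape[0]
    knn = [knn_brute(e, k) for e in embs]
    J = [jaccard_all_pairs(knn[m][0]) for m in range(M)]
    sigma = [
        bandwidth_exhaustive(embs[m], knn[m][0], knn[m][1], J[m], n_bw=n_bw)
        for m in range(M)
    ]
    d_first = [knn[m][1][:, 0] for m in range(M)]

    within = [
        np.array([embs[m][knn[m][0][i]].mean(axis=0) for i in range(n)])
        for m in range(M)
    ]
    cross = {
        (m, nn): np.array([embs[m][knn[nn][0][i]].mean(axis=0) for i in range(n)])
        for m in range(M)
        for nn in range(M)
        if m != nn
    }
    th_w = np.zeros((n, M))
    th_c = {}
    for m in range(M):
        for i in range(n):
            d = np.linalg.norm(embs[m][i] - within[m][i])
            th_w[i, m] = affinity(d, d_first[m][i], sigma[m][i])
        for nn in range(M):
            if nn == m:
                continue
            v = np.zeros(n)
            for i in range(n):
                d = np.linalg.norm(embs[m][i] - cross[(m, nn)][i])
                v[i] = affinity(d, d_first[m][i], sigma[m][i])
            th_c[(m, nn)] = v
    ratios = {key: th_w[:, key[0]] / (th_c[key] + eps) for key in th_c}
    weights = np.zeros((n, M))
    for i in range(n):
        vals = {key: ratios[key][i] for key in ratios}
        mx = max(vals.values())
        es = {key: np.exp(v - mx) for key, v in vals.items()}
        tot = sum(es.values())
        for (m, _), e in es.items():
            weights[i, m] += e / tot

    top_idx = np.empty((n, k), dtype=int)
    top_sim = np.empty((n, k))
    for i in range(n):
        scores = []
        for j in range(n):
            if j == i:
                continue
            s = 0.0
            for m in range(M):
                d = np.linalg.norm(embs[m][j] - embs[m][i])
                s += weights[i, m] * affinity(d, d_first[m][i], sigma[m][i])
            scores.append((-s, j))
        scores.sort()
        top_idx[i] = [j for _, j in scores[:k]]
        top_sim[i] = [-s for s, _ in scores[:k]]
    return {
        "knn": knn,
        "jaccard": J,
        "sigma": sigma,
        "within": within,
        "cross": cross,
        "theta_within": th_w,
        "theta_cross": th_c,
        "ratios": ratios,
        "weights": weights,
        "top_idx": top_idx,
        "top_sim": top_sim,
    }


def mnn_brute(ref, query, k):
    """Mutual nearest neighbors by exhaustive distance sorting."""
    nr, nq = ref.shape[0], query.shape[0]
    k = min(k, nr, nq)
    rq = []
    for r in range(nr):
        d = np.sqrt(((query - ref[r]) ** 2).sum(axis=1))
        rq.append(set(np.argsort(d, kind="stable")[:k].tolist()))
    qr = []
    for q in range(nq):
        d = np.sqrt(((ref - query[q]) ** 2).sum(axis=1))
        qr.append(set(np.argsort(d, kind="stable")[:k].tolist()))
    return {(r, q) for r in range(nr) for q in rq[r] if r in qr[q]}
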