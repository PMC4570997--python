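"""Population-genetic summaries: haplotypes, diversity indices, neutrality
tests, hierarchical AMOVA, and minimum-spanning haplotype networks.

Site filtering here uses *complete deletion*: any column containing a gap,
an N or an IUPAC ambiguity in any sequence is removed before haplotypes or
diversity are computed (the convention of standard haplotype software).
This deliberately differs from the pairwise deletion used for K2P
distances; both conventions are applied where the corresponding original
analyses used them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .seqio import Alignment

# ---------------------------------------------------------------------------
# haplotypes


@dataclass
class HaplotypeTable:
    """Distinct sequences (over complete-deletion columns) with counts."""

    haplotypes: list[str]  # haplotype sequences, ordered H1, H2, ...
    names: list[str]
    counts: list[int]
    members: list[list[str]]  # sequence ids per haplotype
    group_counts: pd.DataFrame  # haplotype x country counts

    @property
    def n_sequences(self) -> int:
        return int(sum(self.counts))

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)


def _complete_deletion(alignment: Alignment) -> np.ndarray:
    """Encoded matrix restricted to columns where every row is plain A/C/G/T."""
    enc = alignment.encoded()
    keep = (enc >= 0).all(axis=0)
    if not keep.any():
        raise ValueError("complete deletion removed every column")
    return enc[:, keep]


def collapse_haplotypes(alignment: Alignment) -> HaplotypeTable:
    """Merge identical sequences after removing gap/ambiguity columns.

    Haplotypes are named H1, H2, ... in order of decreasing count (ties by
    first occurrence); per-country composition is tabulated from record
    metadata (missing countries grouped under "unknown").
    """
    enc = _complete_deletion(alignment)
    keymap: dict[bytes, int] = {}
    members: list[list[str]] = []
    seqs: list[str] = []
    decode = np.array(list("ACGT"))
    for row, rec in zip(enc, alignment.records):
        key = row.tobytes()
        if key not in keymap:
            keymap[key] = len(members)
            members.append([])
            seqs.append("".join(decode[row]))
        members[keymap[key]].append(rec.id)
    order = sorted(range(len(members)), key=lambda i: (-len(members[i]), i))
    seqs = [seqs[i] for i in order]
    members = [members[i] for i in order]
    names = [f"H{i + 1}" for i in range(len(members))]
    country_of = {r.id: (r.country or "unknown") for r in alignment.records}
    countries = sorted({country_of[i] for ms in members for i in ms})
    gc = pd.DataFrame(0, index=names, columns=countries, dtype=int)
    for name, ms in zip(names, members):
        for sid in ms:
            gc.loc[name, country_of[sid]] += 1
    return HaplotypeTable(seqs, names, [len(m) for m in members], members, gc)


# ---------------------------------------------------------------------------
# diversity and neutrality


@dataclass
class DiversityStats:
    n: int
    sites: int  # analyzed (complete-deletion) columns
    S: int  # polymorphic sites
    eta: int  # total mutations (alleles - 1 summed over sites)
    k: float  # mean pairwise differences
    pi: float  # per-site nucleotide diversity
    h: int  # haplotype count
    Hd: float  # haplotype diversity
    tajima_D: float  # NaN when undefined
    fu_li_D: float  # outgroup-polarized; NaN without outgroup or when undefined
    fu_li_Dstar: float

    def as_row(self) -> dict:
        return {
            "n": self.n, "S": self.S, "k": round(self.k, 2), "pi": round(self.pi, 4),
            "h": self.h, "Hd": round(self.Hd, 3),
            "FuLi_D": round(self.fu_li_D, 2) if self.fu_li_D == self.fu_li_D else None,
            "FuLi_Dstar": round(self.fu_li_Dstar, 2) if self.fu_li_Dstar == self.fu_li_Dstar else None,
            "Tajima_D": round(self.tajima_D, 2) if self.tajima_D == self.tajima_D else None,
        }


def _harmonics(n: int) -> tuple[float, float]:
    a1 = float(np.sum(1.0 / np.arange(1, n)))
    a2 = float(np.sum(1.0 / np.arange(1, n) ** 2))
    return a1, a2


def tajimas_d(n: int, S: int, k: float) -> float:
    """Tajima's D from sample size, segregating sites and mean pairwise diffs."""
    if n < 4 or S == 0:
        return float("nan")
    a1, a2 = _harmonics(n)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return float((k - S / a1) / np.sqrt(var)) if var > 0 else float("nan")


def _fu_li_constants(n: int) -> tuple[float, float, float, float]:
    """(u_D, v_D, u_D*, v_D*) for Fu & Li's tests (corrected formulas)."""
    a_n, b_n = _harmonics(n)
    a_n1 = a_n + 1.0 / n
    if n > 2:
        c_n = 2 * (n * a_n - 2 * (n - 1)) / ((n - 1) * (n - 2))
    else:
        c_n = 1.0
    v_D = 1 + a_n**2 / (b_n + a_n**2) * (c_n - (n + 1) / (n - 1))
    u_D = a_n - 1 - v_D
    if n > 2:
        d_n = c_n + (n - 2) / ((n - 1) ** 2) + (2 / (n - 1)) * (
            1.5 - (2 * a_n1 - 3) / (n - 2) - 1.0 / n
        )
    else:
        d_n = 2.0
    v_Ds = ((n / (n - 1)) ** 2 * b_n + a_n**2 * d_n
            - 2 * (n * a_n * (a_n + 1)) / ((n - 1) ** 2)) / (a_n**2 + b_n)
    u_Ds = (n / (n - 1)) * (a_n - n / (n - 1)) - v_Ds
    return u_D, v_D, u_Ds, v_Ds


def fu_li_d(n: int, eta: int, eta_e: int) -> float:
    """Fu & Li's D (outgroup variant): total vs external (derived-singleton) mutations."""
    if n < 3 or eta == 0:
        return float("nan")
    a_n, _ = _harmonics(n)
    u_D, v_D, _, _ = _fu_li_constants(n)
    var = u_D * eta + v_D * eta**2
    return float((eta - a_n * eta_e) / np.sqrt(var)) if var > 0 else float("nan")


def fu_li_dstar(n: int, eta: int, eta_s: int) -> float:
    """Fu & Li's D* (no outgroup): total mutations vs singletons."""
    if n < 3 or eta == 0:
        return float("nan")
    a_n, _ = _harmonics(n)
    _, _, u_Ds, v_Ds = _fu_li_constants(n)
    var = u_Ds * eta + v_Ds * eta**2
    num = (n / (n - 1)) * eta - a_n * eta_s
    return float(num / np.sqrt(var)) if var > 0 else float("nan")


def diversity(alignment: Alignment, outgroup: str | None = None) -> DiversityStats:
    """Diversity indices and neutrality tests on complete-deletion columns.

    ``outgroup`` names a record used only to polarize mutations for
    Fu & Li's D (it is excluded from all indices); without it the D column
    is NaN and only D* is available.
    """
    og_row = None
    records = alignment.records
    if outgroup is not None:
        og = [r for r in records if r.id == outgroup]
        if not og:
            raise ValueError(f"outgroup {outgroup!r} not in alignment")
        records = [r for r in records if r.id != outgroup]
        alignment_in = Alignment(records + og)
        enc_all = _complete_deletion(alignment_in)
        enc, og_row = enc_all[:-1], enc_all[-1]
    else:
        enc = _complete_deletion(Alignment(list(records)))
    n, L = enc.shape
    if n < 2:
        raise ValueError("need >= 2 ingroup sequences")
    # per-site allele counts
    S = 0
    eta = 0
    eta_s = 0
    eta_e = 0
    sum_pair_diff = 0.0
    for col in range(L):
        vals, cnts = np.unique(enc[:, col], return_counts=True)
        if len(vals) > 1:
            S += 1
            eta += len(vals) - 1
            # pairwise differences contributed by this site
            sum_pair_diff += (n * (n - 1) - np.sum(cnts * (cnts - 1))) / 2
            singles = vals[cnts == 1]
            eta_s += len(singles)
            if og_row is not None:
                anc = og_row[col]
                eta_e += int(np.sum([1 for v in singles if v != anc]))
    npairs = n * (n - 1) / 2
    k = sum_pair_diff / npairs
    pi = k / L
    # haplotypes on the same column set
    keys = {}
    for row in enc:
        keys.setdefault(row.tobytes(), 0)
        keys[row.tobytes()] += 1
    h = len(keys)
    freqs = np.array(list(keys.values())) / n
    Hd = float(n / (n - 1) * (1 - np.sum(freqs**2)))
    return DiversityStats(
        n=n, sites=L, S=S, eta=eta, k=float(k), pi=float(pi), h=h, Hd=Hd,
        tajima_D=tajimas_d(n, S, k),
        fu_li_D=fu_li_d(n, eta, eta_e) if og_row is not None else float("nan"),
        fu_li_Dstar=fu_li_dstar(n, eta, eta_s),
    )


def diversity_table(
    alignment: Alignment, partition=None, outgroup: str | None = None
) -> pd.DataFrame:
    """Per-group diversity table ("all" row plus one row per group)."""
    assignment = getattr(partition, "assignment", partition) if partition else None
    rows = {"all": diversity(alignment, outgroup)}
    if assignment:
        for g in sorted(set(assignment.values())):
            ids = [i for i, v in assignment.items() if v == g]
            sub = alignment.subset(ids + ([outgroup] if outgroup else []))
            if len(sub) - (1 if outgroup else 0) >= 2:
                rows[g] = diversity(sub, outgroup)
    return pd.DataFrame({name: st.as_row() for name, st in rows.items()}).T


# ---------------------------------------------------------------------------
# AMOVA


@dataclass
class AmovaResult:
    """Three-level AMOVA: clades (groups) / countries (populations) / individuals."""

    ss: dict[str, float]  # sums of squares per stratum
    df: dict[str, int]
    sigma2: dict[str, float]  # variance components a (among groups), b, c
    percent: dict[str, float]
    phi_CT: float
    phi_SC: float
    phi_ST: float
    p_values: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key, src in [
            ("a", "Among groups"), ("b", "Among populations within groups"),
            ("c", "Within populations"),
        ]:
            rows.append({
                "source": src, "df": self.df[key], "sum_of_squares": self.ss[key],
                "variance_component": self.sigma2[key], "percent": self.percent[key],
            })
        df = pd.DataFrame(rows)
        df["fixation_index"] = [self.phi_CT, self.phi_SC, self.phi_ST]
        df["p_value"] = [
            self.p_values.get("phi_CT"), self.p_values.get("phi_SC"),
            self.p_values.get("phi_ST"),
        ]
        return df


def pairwise_difference_matrix(alignment: Alignment) -> np.ndarray:
    """Hamming differences over complete-deletion columns (AMOVA distance)."""
    enc = _complete_deletion(alignment)
    n = enc.shape[0]
    d = np.zeros((n, n))
    for i in range(n - 1):
        diff = (enc[i] != enc[i + 1 :]).sum(axis=1)
        d[i, i + 1 :] = diff
        d[i + 1 :, i] = diff
    return d


def _amova_components(d2: np.ndarray, group_codes: np.ndarray, pop_codes: np.ndarray):
    """Variance components from squared distances for one labelling."""
    N = len(group_codes)
    groups = np.unique(group_codes)
    pops = np.unique(pop_codes)
    G, P = len(groups), len(pops)

    def ssd(mask: np.ndarray) -> float:
        m = int(mask.sum())
        return float(d2[np.ix_(mask, mask)].sum() / (2 * m)) if m else 0.0

    ssd_total = ssd(np.ones(N, dtype=bool))
    ssd_wp = sum(ssd(pop_codes == p) for p in pops)
    ssd_groups = sum(ssd(group_codes == g) for g in groups)
    ssd_ap_wg = ssd_groups - ssd_wp
    ssd_ag = ssd_total - ssd_groups
    df_ag, df_ap, df_wp = G - 1, P - G, N - P
    sigma_c = ssd_wp / df_wp if df_wp > 0 else float("nan")
    # expected-mean-square coefficients
    n_pg = {g: pop_codes[group_codes == g] for g in groups}
    sum_npg2_over_ng = 0.0
    for g in groups:
        pops_g, cnt = np.unique(n_pg[g], return_counts=True)
        sum_npg2_over_ng += float(np.sum(cnt**2)) / cnt.sum()
    _, pop_sizes = np.unique(pop_codes, return_counts=True)
    _, group_sizes = np.unique(group_codes, return_counts=True)
    sum_np2_over_N = float(np.sum(pop_sizes**2)) / N
    n1 = (N - sum_npg2_over_ng) / df_ap if df_ap > 0 else float("nan")
    n2 = (sum_npg2_over_ng - sum_np2_over_N) / df_ag if df_ag > 0 else float("nan")
    n3 = (N - float(np.sum(group_sizes**2)) / N) / df_ag if df_ag > 0 else float("nan")
    if df_ap > 0:
        ms_ap = ssd_ap_wg / df_ap
        sigma_b = (ms_ap - sigma_c) / n1
    else:
        sigma_b = float("nan")
    if df_ag > 0:
        ms_ag = ssd_ag / df_ag
        sb = 0.0 if sigma_b != sigma_b else sigma_b
        sigma_a = (ms_ag - sigma_c - n2 * sb) / n3
    else:
        sigma_a = float("nan")
    return (ssd_ag, ssd_ap_wg, ssd_wp), (df_ag, df_ap, df_wp), (sigma_a, sigma_b, sigma_c)


def _phis(sigma_a: float, sigma_b: float, sigma_c: float) -> tuple[float, float, float]:
    sa = 0.0 if sigma_a != sigma_a else sigma_a
    sb = 0.0 if sigma_b != sigma_b else sigma_b
    total = sa + sb + sigma_c
    phi_ct = sigma_a / total if sigma_a == sigma_a else float("nan")
    phi_sc = sigma_b / (sb + sigma_c) if sigma_b == sigma_b else float("nan")
    phi_st = (sa + sb) / total
    return phi_ct, phi_sc, phi_st


def amova(
    data,
    groups: dict[str, str],
    populations: dict[str, str],
    n_permutations: int = 1000,
    seed: int | None = None,
) -> AmovaResult:
    """Hierarchical AMOVA (groups / populations / individuals).

    ``data`` is an :class:`~cladedelim.seqio.Alignment` (pairwise nucleotide
    differences are computed with complete deletion) or a precomputed
    difference matrix paired with ordered ids as ``(matrix, ids)``.
    Significance is assessed by permutation: individuals across populations
    (phi_ST), individuals among populations within their group (phi_SC),
    whole populations among groups (phi_CT);
    p = (#permutations at least as extreme + 1) / (n + 1).
    """
    if isinstance(data, Alignment):
        ids = data.ids
        d = pairwise_difference_matrix(data)
    else:
        d, ids = data
        d = np.asarray(d, dtype=float)
    missing = [i for i in ids if i not in groups or i not in populations]
    if missing:
        raise ValueError(f"ids without group/population labels: {missing[:5]}")
    d2 = d**2
    gidx = {g: i for i, g in enumerate(sorted(set(groups.values())))}
    pidx = {p: i for i, p in enumerate(sorted(set(populations.values())))}
    gcodes = np.array([gidx[groups[i]] for i in ids])
    pcodes = np.array([pidx[populations[i]] for i in ids])
    if len(gidx) < 2:
        raise ValueError("need >= 2 groups")
    ss, df, (sa, sb, sc) = _amova_components(d2, gcodes, pcodes)
    phi_ct, phi_sc, phi_st = _phis(sa, sb, sc)
    total = sum(x for x in (sa, sb, sc) if x == x)
    percent = {
        "a": 100 * sa / total if sa == sa else float("nan"),
        "b": 100 * sb / total if sb == sb else float("nan"),
        "c": 100 * sc / total,
    }
    pvals: dict[str, float] = {}
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        group_of_pop = {}
        for i, pid in enumerate(pcodes):
            group_of_pop[pid] = gcodes[i]
        hits = {"phi_ST": 0, "phi_SC": 0, "phi_CT": 0}
        n = len(ids)
        for _ in range(n_permutations):
            # phi_ST: shuffle individuals across the whole structure
            perm = rng.permutation(n)
            _, _, s = _amova_components(d2, gcodes[perm], pcodes[perm])
            if _phis(*s)[2] >= phi_st - 1e-12:
                hits["phi_ST"] += 1
            # phi_SC: shuffle individuals among populations within each group
            perm2 = np.arange(n)
            for g in np.unique(gcodes):
                members = np.where(gcodes == g)[0]
                perm2[members] = members[rng.permutation(len(members))]
            _, _, s = _amova_components(d2, gcodes, pcodes[perm2])
            stat = _phis(*s)[1]
            if stat == stat and phi_sc == phi_sc and stat >= phi_sc - 1e-12:
                hits["phi_SC"] += 1
            # phi_CT: shuffle whole populations among groups
            upops = np.unique(pcodes)
            gp = np.array([group_of_pop[p] for p in upops])
            gp_perm = gp[rng.permutation(len(gp))]
            gmap = dict(zip(upops, gp_perm))
            _, _, s = _amova_components(d2, np.array([gmap[p] for p in pcodes]), pcodes)
            stat = _phis(*s)[0]
            if stat == stat and phi_ct == phi_ct and stat >= phi_ct - 1e-12:
                hits["phi_CT"] += 1
        for key in hits:
            pvals[key.replace("phi_", "phi_")] = (hits[key] + 1) / (n_permutations + 1)
        pvals = {"phi_ST": pvals["phi_ST"], "phi_SC": pvals["phi_SC"], "phi_CT": pvals["phi_CT"]}
    return AmovaResult(
        ss={"a": ss[0], "b": ss[1], "c": ss[2]},
        df={"a": df[0], "b": df[1], "c": df[2]},
        sigma2={"a": sa, "b": sb, "c": sc},
        percent=percent,
        phi_CT=phi_ct, phi_SC=phi_sc, phi_ST=phi_st,
        p_values=pvals,
    )


# ---------------------------------------------------------------------------
# minimum spanning network


def msn(table: HaplotypeTable, epsilon: int = 0) -> nx.Graph:
    """Minimum spanning network over haplotypes.

    Nodes are haplotypes (attributes: count, per-country composition);
    an edge (u, v) with Hamming distance w is kept iff
    w <= minimax-path-weight(u, v) + epsilon, where the minimax path weight
    is taken over one MST (the largest step unavoidable when connecting u
    and v). With epsilon = 0 this is exactly the union of all MSTs.
    """
    n = table.n_haplotypes
    g = nx.Graph()
    for name, count in zip(table.names, table.counts):
        comp = table.group_counts.loc[name]
        g.add_node(name, count=int(count), countries={c: int(v) for c, v in comp.items() if v})
    if n == 1:
        return g
    enc = np.array([[ord(c) for c in h] for h in table.haplotypes])
    full = nx.Graph()
    for i in range(n):
        for j in range(i + 1, n):
            w = int((enc[i] != enc[j]).sum())
            full.add_edge(table.names[i], table.names[j], weight=w)
    mst = nx.minimum_spanning_tree(full, weight="weight")
    # minimax path weight between all node pairs, from the MST
    for u, v, data in full.edges(data=True):
        path = nx.shortest_path(mst, u, v)
        minimax = max(mst[a][b]["weight"] for a, b in zip(path, path[1:]))
        if data["weight"] <= minimax + epsilon:
            g.add_edge(u, v, steps=data["weight"])
    return g


def msn_edgelist(g: nx.Graph) -> pd.DataFrame:
    rows = [{"h1": u, "h2": v, "steps": d["steps"]} for u, v, d in sorted(g.edges(data=True))]
    return pd.DataFrame(rows, columns=["h1", "h2", "steps"])


def write_network(g: nx.Graph, path) -> None:
    """GraphML export (country composition flattened to a string attribute)."""
    h = nx.Graph()
    for node, data in g.nodes(data=True):
        comp = ";".join(f"{c}:{v}" for c, v in sorted(data.get("countries", {}).items()))
        h.add_node(node, count=data.get("count", 0), countries=comp)
    for u, v, data in g.edges(data=True):
        h.add_edge(u, v, steps=data["steps"])
    nx.write_graphml(h, path)
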