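"""Canonical miRNA seed-site prediction and scoring on 3'UTRs.

Three layers of evidence are combined:

1. **Seed grammar** -- exact Watson-Crick complementarity (no wobble in the
   seed) of miRNA positions 2-7 (6mer) or 2-8 (7mer-m8) against the UTR,
   with an A in the UTR opposite miRNA position 1 upgrading each to
   7mer-A1 / 8mer.  Each 6mer anchor is reported once with its maximal type.
2. **Hybridization alignment score** -- a seed-weighted local alignment
   (miRanda-style, on this package's own scale) of the reversed miRNA
   against the UTR window 5' of the site: Watson-Crick +5, G:U wobble +2,
   mismatch -4, gap open -8, gap extend -2, pair/mismatch terms doubled for
   miRNA positions 2-8.
3. **Context-like score** -- an additive per-site repression score with the
   TargetScan feature directions (site type >> AU flank content >> distance
   from the UTR ends); more negative predicts stronger repression.

A gene-level call passes when the summed alignment score over
non-overlapping sites reaches a per-miRNA threshold (a fraction of the
perfect-duplex score, the analog of an absolute tool-scale cutoff) OR the
best context score is negative with a 7mer-or-better site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import InputError
from .seq import complement, normalize_rna, reverse_complement

SITE_LENGTH = {"6mer": 6, "7mer-A1": 7, "7mer-m8": 7, "8mer": 8}
SEVEN_OR_BETTER = {"7mer-A1", "7mer-m8", "8mer"}

CONTEXT_BASE = {"8mer": -0.31, "7mer-m8": -0.16, "7mer-A1": -0.10, "6mer": -0.03}

WC_SCORE = 5.0
WOBBLE_SCORE = 2.0
MISMATCH_SCORE = -4.0
GAP_OPEN = -8.0
GAP_EXTEND = -2.0
MAX_WINDOW = 80

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}


@dataclass
class MiRNARecord:
    """A mature miRNA; the seed is positions 2-8 of the 5'->3' sequence."""

    id: str
    mature_seq: str

    def __post_init__(self) -> None:
        self.mature_seq = normalize_rna(self.mature_seq, name=f"miRNA {self.id}")
        if len(self.mature_seq) < 16:
            raise InputError(f"miRNA {self.id}: mature sequence shorter than 16 nt")

    @property
    def seed(self) -> str:
        """Heptamer at positions 2-8 (0-based slice [1:8])."""
        return self.mature_seq[1:8]


@dataclass
class TargetSite:
    """One located seed-match site on a UTR (0-based half-open start)."""

    gene_id: str
    mirna_id: str
    utr_start: int
    site_type: str
    align_score: float = field(default=float("nan"))
    context_score: float = field(default=float("nan"))

    @property
    def length(self) -> int:
        return SITE_LENGTH[self.site_type]

    @property
    def utr_end(self) -> int:
        return self.utr_start + self.length


@dataclass
class TargetCall:
    """Gene-level targeting decision for one (gene, miRNA)."""

    gene_id: str
    mirna_id: str
    total_align_score: float
    best_context_score: float
    n_sites: int
    passes: bool
    best_site_type: str | None = None


def find_seed_sites(utr_seq: str, mirna: MiRNARecord, gene_id: str = "") -> list[TargetSite]:
    """All canonical seed matches of a miRNA on a UTR, maximal type each.

    Anchored on 6mer (seed positions 2-7) matches; an adjacent match to
    position 8 on the 5' side and/or an A opposite position 1 on the 3'
    side upgrades the type.  Overlapping matches at distinct anchors are
    all reported; resolution happens in :func:`call_targets`.
    """
    utr = normalize_rna(utr_seq, name=f"UTR {gene_id or '?'}")
    m = mirna.mature_seq
    core = reverse_complement(m[1:7])  # site bases pairing positions 2-7
    m8c = complement(m[7])  # UTR base pairing position 8, 5' of the core
    sites: list[TargetSite] = []
    q = utr.find(core)
    while q != -1:
        has_m8 = q > 0 and utr[q - 1] == m8c
        has_a1 = q + 6 < len(utr) and utr[q + 6] == "A"
        if has_m8 and has_a1:
            site_type, start = "8mer", q - 1
        elif has_m8:
            site_type, start = "7mer-m8", q - 1
        elif has_a1:
            site_type, start = "7mer-A1", q
        else:
            site_type, start = "6mer", q
        sites.append(TargetSite(gene_id, mirna.id, start, site_type))
        q = utr.find(core, q + 1)
    return sites


def _pair_score(mir_base: str, utr_base: str, seed: bool) -> float:
    if (mir_base, utr_base) in _WC:
        s = WC_SCORE
    elif (mir_base, utr_base) in _WOBBLE:
        s = WOBBLE_SCORE
    else:
        s = MISMATCH_SCORE
    return 2.0 * s if seed else s


def hybrid_align_score(mirna: MiRNARecord, utr_window: str) -> float:
    """Best seed-weighted local alignment of the miRNA against a UTR window.

    The miRNA is reversed (3'->5') so that the duplex is antiparallel
    against the 5'->3' window.  Affine gaps: the first base of a gap costs
    the open penalty, each further base the extend penalty.  Score >= 0
    (local-alignment floor).
    """
    window = normalize_rna(utr_window, name="UTR window")
    if len(window) > MAX_WINDOW:
        raise InputError(f"window longer than {MAX_WINDOW} nt; slice windows before scoring")
    a = mirna.mature_seq[::-1]
    L = len(a)
    # original 1-based miRNA position of reversed index i (0-based) is L - i
    seed_flags = [2 <= (L - i) <= 8 for i in range(L)]
    n, m = L, len(window)
    NEG = -1e18
    best = 0.0
    prev_m = [0.0] * (m + 1)
    prev_x = [NEG] * (m + 1)
    prev_y = [NEG] * (m + 1)
    for i in range(1, n + 1):
        cur_m = [0.0] * (m + 1)
        cur_x = [NEG] * (m + 1)
        cur_y = [NEG] * (m + 1)
        for j in range(1, m + 1):
            sub = _pair_score(a[i - 1], window[j - 1], seed_flags[i - 1])
            cur_m[j] = max(
                0.0,
                max(prev_m[j - 1], prev_x[j - 1], prev_y[j - 1], 0.0) + sub,
            )
            # gap in the window (consumes a miRNA base)
            cur_x[j] = max(prev_m[j] + GAP_OPEN, prev_x[j] + GAP_EXTEND)
            # gap in the miRNA (consumes a window base)
            cur_y[j] = max(cur_m[j - 1] + GAP_OPEN, cur_y[j - 1] + GAP_EXTEND)
            if cur_m[j] > best:
                best = cur_m[j]
        prev_m, prev_x, prev_y = cur_m, cur_x, cur_y
    return best


def perfect_duplex_score(mirna: MiRNARecord) -> float:
    """Alignment score of the miRNA against its own reverse complement."""
    return hybrid_align_score(mirna, reverse_complement(mirna.mature_seq))


def context_like_score(
    site: TargetSite,
    utr_seq: str,
    w_au: float = 0.1,
    w_pos: float = 0.1,
) -> float:
    """Additive per-site repression score; more negative = stronger.

    ``score = base(site_type) - w_au * AU30 - w_pos * prox`` where ``AU30``
    is the A/U fraction of up to 30 nt flanking each side of the site
    (truncated at the UTR ends) and ``prox`` rises linearly from 0 for a
    site equidistant from both UTR ends to 1 for a site flush against
    either end: ``prox = max(0, 1 - min(d5, d3) / ((L - site_len) / 2))``
    with d5/d3 the gaps between the site and the 5'/3' UTR ends.
    """
    utr = normalize_rna(utr_seq, name=f"UTR {site.gene_id or '?'}")
    L = len(utr)
    start, end = site.utr_start, site.utr_end
    if start < 0 or end > L:
        raise InputError(
            f"site [{start}, {end}) outside UTR of length {L} for {site.gene_id}/{site.mirna_id}"
        )
    flank = utr[max(0, start - 30) : start] + utr[end : end + 30]
    au30 = (flank.count("A") + flank.count("U")) / len(flank) if flank else 0.0
    half = (L - site.length) / 2.0
    d5 = start
    d3 = L - end
    prox = 1.0 if half <= 0 else max(0.0, 1.0 - min(d5, d3) / half)
    return CONTEXT_BASE[site.site_type] - w_au * au30 - w_pos * prox


def score_sites(
    sites: list[TargetSite],
    utr_seq: str,
    mirna: MiRNARecord,
    w_au: float = 0.1,
    w_pos: float = 0.1,
    window_upstream: int = 32,
) -> list[TargetSite]:
    """Fill ``align_score`` and ``context_score`` in place for each site.

    The alignment window spans ``window_upstream`` nt 5' of the site
    through the site end: antiparallel pairing places the miRNA 3' tail
    upstream of the seed match on the UTR.
    """
    utr = normalize_rna(utr_seq, name=f"UTR {sites[0].gene_id if sites else '?'}")
    for site in sites:
        window = utr[max(0, site.utr_end - site.length - window_upstream) : site.utr_end]
        site.align_score = hybrid_align_score(mirna, window)
        site.context_score = context_like_score(site, utr, w_au=w_au, w_pos=w_pos)
    return sites


def call_targets(
    gene_id: str,
    mirna: MiRNARecord,
    sites: list[TargetSite],
    align_min: float | None = None,
    align_min_frac: float = 0.9,
) -> TargetCall:
    """Gene-level pass decision under the dual-threshold rule.

    Overlapping sites are resolved greedily by descending alignment score
    (ties: leftmost).  ``passes`` iff the summed alignment score over
    retained sites reaches ``align_min`` (default: ``align_min_frac`` times
    the miRNA's perfect-duplex score) OR the best (minimum) context score
    is negative and its site is 7mer-A1/7mer-m8/8mer.
    """
    for s in sites:
        if s.gene_id != gene_id or s.mirna_id != mirna.id:
            raise InputError(
                f"site for ({s.gene_id}, {s.mirna_id}) mixed into call for ({gene_id}, {mirna.id})"
            )
    if align_min is None:
        align_min = align_min_frac * perfect_duplex_score(mirna)
    retained: list[TargetSite] = []
    order = sorted(sites, key=lambda s: (-s.align_score, s.utr_start))
    for cand in order:
        if all(
            cand.utr_end <= kept.utr_start or cand.utr_start >= kept.utr_end
            for kept in retained
        ):
            retained.append(cand)
    if not retained:
        return TargetCall(gene_id, mirna.id, 0.0, float("inf"), 0, False)
    total_align = sum(s.align_score for s in retained)
    best = min(retained, key=lambda s: (s.context_score, s.utr_start))
    passes = total_align >= align_min or (
        best.context_score < 0.0 and best.site_type in SEVEN_OR_BETTER
    )
    return TargetCall(
        gene_id,
        mirna.id,
        total_align,
        best.context_score,
        len(retained),
        passes,
        best.site_type,
    )


def scan_gene(
    gene_id: str,
    utr_seq: str,
    mirna: MiRNARecord,
    w_au: float = 0.1,
    w_pos: float = 0.1,
    align_min: float | None = None,
    align_min_frac: float = 0.9,
) -> tuple[list[TargetSite], TargetCall]:
    """Find, score and call all sites of one miRNA on one UTR."""
    sites = find_seed_sites(utr_seq, mirna, gene_id=gene_id)
    score_sites(sites, utr_seq, mirna, w_au=w_au, w_pos=w_pos)
    call = call_targets(
        gene_id, mirna, sites, align_min=align_min, align_min_frac=align_min_frac
    )
    return sites, call
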