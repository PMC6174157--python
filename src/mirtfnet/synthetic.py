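"""Synthetic paired tumor/normal miRNA + mRNA cohorts with planted structure.

The generator emulates the structure of a small paired oncology sequencing
study: a handful of tumor/adjacent-normal pairs, an mRNA count matrix over
thousands of genes (a subset flagged as transcription factors), a miRNA
count matrix over a few hundred mature miRNAs, and a planted cooperative
suppression motif -- a set of co-upregulated miRNAs that all carry seed
sites in the 3'UTR of one hub TF, whose tumor expression is multiplicatively
suppressed per targeting miRNA.

Counts are negative-binomial (gamma-Poisson) around library-scaled
log-normal baselines.  Everything is deterministic given ``rng_seed``; each
generation stage draws from its own seed stream derived as
``(rng_seed, stage_index)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, GenerationError
from .quantify import CountMatrix
from .seq import reverse_complement
from .targets import MiRNARecord
from . import io as mio

_ALPHABET = np.frombuffer(b"ACGU", dtype=np.uint8)

TF_TERM_ID = "GO:0003700"
TF_TERM_NAME = "DNA-binding transcription factor activity"


@dataclass
class SimulationConfig:
    """All knobs of the cohort generator.

    Defaults reproduce the study-scale conditions: 4 pairs, 2000 genes of
    which 150 TFs, 300 miRNAs with 40 planted co-upregulated at fold change
    4, one hub TF carrying seed sites for 25 of them, dispersion 0.05, and
    scaled-down library sizes of 1-2M reads.
    """

    n_genes: int = 2000
    n_tfs: int = 150
    n_mirnas: int = 300
    n_pairs: int = 4
    utr_length_range: tuple[int, int] = (250, 700)
    nb_dispersion: float = 0.05
    baseline_log_mean: tuple[float, float] = (math.log(500.0), 1.0)
    mirna_baseline_log_mean: tuple[float, float] = (math.log(3000.0), 1.2)
    baseline_mean_floor: float = 200.0
    planted_baseline_range: tuple[float, float] = (250.0, 800.0)
    planted_up_mirnas: int = 40
    planted_down_mirnas: int = 5
    planted_mirna_fc: float = 4.0
    hub_site_mirnas: int = 25
    target_suppression_fc: float = 0.5
    suppression_floor: float = 0.1
    targets_per_mirna: int = 12
    target_pool_genes: int = 40
    background_de_fraction: float = 0.10
    background_log2fc_sd: float = 1.0
    library_size_range: tuple[int, int] = (1_000_000, 2_000_000)
    n_go_terms: int = 40
    go_terms_per_gene: tuple[int, int] = (1, 4)
    rng_seed: int = 0

    def validate(self) -> None:
        def positive(name):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")

        for name in ("n_genes", "n_mirnas", "nb_dispersion", "planted_mirna_fc"):
            positive(name)
        for name in (
            "n_tfs",
            "planted_up_mirnas",
            "planted_down_mirnas",
            "hub_site_mirnas",
            "targets_per_mirna",
            "target_pool_genes",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.n_pairs < 2:
            raise ConfigError(f"n_pairs must be >= 2, got {self.n_pairs}")
        if self.n_tfs > self.n_genes:
            raise ConfigError(f"n_tfs ({self.n_tfs}) exceeds n_genes ({self.n_genes})")
        if self.hub_site_mirnas > self.planted_up_mirnas:
            raise ConfigError(
                f"hub_site_mirnas ({self.hub_site_mirnas}) exceeds planted_up_mirnas "
                f"({self.planted_up_mirnas})"
            )
        if self.planted_up_mirnas + self.planted_down_mirnas > self.n_mirnas:
            raise ConfigError("planted miRNAs exceed n_mirnas")
        for name in (
            "utr_length_range",
            "library_size_range",
            "go_terms_per_gene",
            "planted_baseline_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi or lo <= 0:
                raise ConfigError(f"{name} must be a non-empty positive interval, got ({lo}, {hi})")
        if not 0.0 <= self.background_de_fraction <= 1.0:
            raise ConfigError(
                f"background_de_fraction must be in [0, 1], got {self.background_de_fraction}"
            )
        # 1.0 is allowed so a global-null cohort can be constructed; values
        # above 1/1.5 leave targets below the default calling threshold.
        if self.target_suppression_fc <= 0 or self.target_suppression_fc > 1.0:
            raise ConfigError(
                f"target_suppression_fc must be in (0, 1], got {self.target_suppression_fc}"
            )
        if not 0 < self.suppression_floor <= 1:
            raise ConfigError(f"suppression_floor must be in (0, 1], got {self.suppression_floor}")


@dataclass
class GeneRecord:
    gene_id: str
    utr_seq: str
    exonic_length: int
    is_tf: bool
    go_terms: list[str] = field(default_factory=list)


@dataclass
class SyntheticTruth:
    """Planted effects and the target map, for parameter-recovery tests."""

    up_mirna_ids: set[str]
    down_mirna_ids: set[str]
    target_map: dict[str, list[tuple[str, int]]]
    hub_gene_id: str
    per_pair_effects: dict[str, dict[str, float]] = field(default_factory=dict)

    def true_edges(self) -> set[tuple[str, str]]:
        """All planted (up-miRNA, suppressed gene) pairs."""
        return {
            (m, g)
            for m in self.up_mirna_ids
            for g, _ in self.target_map.get(m, [])
        }

    def to_json(self) -> str:
        payload = {
            "up_mirna_ids": sorted(self.up_mirna_ids),
            "down_mirna_ids": sorted(self.down_mirna_ids),
            "target_map": {
                m: [[g, int(p)] for g, p in sites]
                for m, sites in sorted(self.target_map.items())
            },
            "hub_gene_id": self.hub_gene_id,
            "per_pair_effects": {
                pair: {f: float(v) for f, v in sorted(effects.items())}
                for pair, effects in sorted(self.per_pair_effects.items())
            },
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        return cls(
            up_mirna_ids=set(d["up_mirna_ids"]),
            down_mirna_ids=set(d["down_mirna_ids"]),
            target_map={
                m: [(g, int(p)) for g, p in sites] for m, sites in d["target_map"].items()
            },
            hub_gene_id=d["hub_gene_id"],
            per_pair_effects={
                pair: dict(effects) for pair, effects in d.get("per_pair_effects", {}).items()
            },
        )


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(config.rng_seed), stage])


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _ALPHABET[rng.integers(0, 4, size=length)].tobytes().decode()


def generate_transcriptome(config: SimulationConfig) -> list[GeneRecord]:
    """Gene records: id, random 3'UTR, exonic length, TF flag, GO terms."""
    config.validate()
    rng = _rng(config, 1)
    n = config.n_genes
    width = len(str(n))
    lo, hi = config.utr_length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    cds = rng.integers(300, 3001, size=n)
    tf_idx = set(rng.choice(n, size=config.n_tfs, replace=False).tolist())
    tlo, thi = config.go_terms_per_gene
    genes = []
    for i in range(n):
        gene_id = f"G{i + 1:0{width}d}"
        n_terms = int(rng.integers(tlo, thi + 1))
        terms = sorted(
            f"GO:{t + 10_000_000:d}"
            for t in rng.choice(config.n_go_terms, size=min(n_terms, config.n_go_terms), replace=False)
        )
        is_tf = i in tf_idx
        if is_tf:
            terms.append(TF_TERM_ID)
        genes.append(
            GeneRecord(
                gene_id=gene_id,
                utr_seq=_random_seq(rng, int(lengths[i])),
                exonic_length=int(lengths[i] + cds[i]),
                is_tf=is_tf,
                go_terms=terms,
            )
        )
    return genes


def generate_mirnome(config: SimulationConfig) -> list[MiRNARecord]:
    """Mature miRNA records, lengths 19-23 nt.

    The first ``planted_up_mirnas`` records are the cohort's co-upregulated
    set and are drawn with pairwise-distinct seed heptamers (positions 2-8);
    the next ``planted_down_mirnas`` are the down-regulated set.
    """
    config.validate()
    if config.planted_up_mirnas > 4**7:
        raise GenerationError(
            f"cannot draw {config.planted_up_mirnas} distinct seed heptamers"
        )
    rng = _rng(config, 2)
    width = len(str(config.n_mirnas))
    records = []
    seen_seeds: set[str] = set()
    for i in range(config.n_mirnas):
        mirna_id = f"miR-{i + 1:0{width}d}"
        planted_up = i < config.planted_up_mirnas
        for attempt in range(10_000):
            seq = _random_seq(rng, int(rng.integers(19, 24)))
            if not planted_up or seq[1:8] not in seen_seeds:
                break
        else:  # pragma: no cover - astronomically unlikely below capacity
            raise GenerationError("failed to draw a distinct seed heptamer")
        if planted_up:
            seen_seeds.add(seq[1:8])
        records.append(MiRNARecord(mirna_id, seq))
    return records


def _site_for(mirna: MiRNARecord) -> str:
    """The strongest canonical site: seed 2-8 complement plus the A1 anchor."""
    return reverse_complement(mirna.mature_seq[1:8]) + "A"


def plant_target_sites(
    genes: list[GeneRecord],
    mirnas: list[MiRNARecord],
    config: SimulationConfig,
) -> tuple[list[GeneRecord], SyntheticTruth]:
    """Write 8mer seed sites into UTRs and return the modified genes + truth.

    The hub is the TF with the longest UTR; the first ``hub_site_mirnas``
    up-miRNAs each get one non-overlapping site in it.  Every up-miRNA
    additionally receives ``targets_per_mirna`` sites spread over random
    non-hub genes.  Sites never overlap one another.
    """
    config.validate()
    rng = _rng(config, 3)
    up_ids = [m.id for m in mirnas[: config.planted_up_mirnas]]
    down_ids = [
        m.id
        for m in mirnas[
            config.planted_up_mirnas : config.planted_up_mirnas + config.planted_down_mirnas
        ]
    ]
    by_id = {m.id: m for m in mirnas}
    genes = [replace(g) for g in genes]
    gene_index = {g.gene_id: i for i, g in enumerate(genes)}
    utrs = {g.gene_id: bytearray(g.utr_seq.encode()) for g in genes}
    occupied: dict[str, list[tuple[int, int]]] = {g.gene_id: [] for g in genes}

    tf_genes = [g for g in genes if g.is_tf]
    if not tf_genes:
        if config.hub_site_mirnas > 0:
            raise GenerationError("hub sites requested but no TF genes exist")
        hub_gene_id = ""
    else:
        hub = max(tf_genes, key=lambda g: (len(g.utr_seq), g.gene_id))
        hub_gene_id = hub.gene_id
        if len(hub.utr_seq) < 8 * config.hub_site_mirnas:
            raise GenerationError(
                f"hub UTR of {len(hub.utr_seq)} nt cannot host "
                f"{config.hub_site_mirnas} non-overlapping 8mer sites"
            )

    def place(gene_id: str, site: str) -> int:
        utr = utrs[gene_id]
        L = len(utr)
        if L < len(site):
            raise GenerationError(f"UTR of {gene_id} too short to host a site")
        def free(pos: int) -> bool:
            return all(pos + len(site) <= a or pos >= b for a, b in occupied[gene_id])

        for _ in range(200):
            pos = int(rng.integers(0, L - len(site) + 1))
            if free(pos):
                break
        else:
            # dense UTR: deterministic scan from a random offset
            offset = int(rng.integers(0, L - len(site) + 1))
            for shift in range(L - len(site) + 1):
                pos = (offset + shift) % (L - len(site) + 1)
                if free(pos):
                    break
            else:
                raise GenerationError(
                    f"UTR of {gene_id} too short to host another non-overlapping site"
                )
        utr[pos : pos + len(site)] = site.encode()
        occupied[gene_id].append((pos, pos + len(site)))
        return pos

    target_map: dict[str, list[tuple[str, int]]] = {m: [] for m in up_ids}
    for mirna_id in up_ids[: config.hub_site_mirnas]:
        pos = place(hub_gene_id, _site_for(by_id[mirna_id]))
        target_map[mirna_id].append((hub_gene_id, pos))
    # Up-miRNA targets are drawn from a shared co-target pool: co-upregulated
    # miRNAs convergently hit an overlapping gene set, so each targeted gene
    # carries sites for several miRNAs (cooperative suppression).
    non_hub = [g.gene_id for g in genes if g.gene_id != hub_gene_id]
    pool_size = min(config.target_pool_genes, len(non_hub))
    pool = (
        [non_hub[int(i)] for i in rng.choice(len(non_hub), size=pool_size, replace=False)]
        if pool_size
        else []
    )
    for mirna_id in up_ids:
        if config.targets_per_mirna == 0 or not pool:
            continue
        chosen = rng.choice(
            len(pool), size=min(config.targets_per_mirna, len(pool)), replace=False
        )
        for gi in chosen:
            pos = place(pool[int(gi)], _site_for(by_id[mirna_id]))
            target_map[mirna_id].append((pool[int(gi)], pos))

    for gene_id, utr in utrs.items():
        genes[gene_index[gene_id]].utr_seq = utr.decode()
    truth = SyntheticTruth(
        up_mirna_ids=set(up_ids),
        down_mirna_ids=set(down_ids),
        target_map=target_map,
        hub_gene_id=hub_gene_id,
    )
    return genes, truth


def _sample_layout(config: SimulationConfig) -> tuple[list[str], list[str], list[str]]:
    pairs = [f"P{i + 1}" for i in range(config.n_pairs)]
    sample_ids, conditions = [], []
    for p in pairs:
        sample_ids += [f"{p}_T", f"{p}_N"]
        conditions += ["tumor", "normal"]
    return pairs, sample_ids, conditions


def simulate_counts(
    genes: list[GeneRecord],
    mirnas: list[MiRNARecord],
    truth: SyntheticTruth,
    config: SimulationConfig,
) -> tuple[CountMatrix, CountMatrix]:
    """Draw NB counts for both matrices; fills ``truth.per_pair_effects``.

    Expected count of feature i in sample j is
    ``baseline_i * effect_ij * L_j / sum(baselines)`` with L_j the sample's
    target library size; tumor effects are the planted miRNA fold change,
    the per-targeting-miRNA multiplicative gene suppression (floored), and
    a log-normal background fold change on a random feature subset.
    """
    config.validate()
    rng = _rng(config, 4)
    pairs, sample_ids, conditions = _sample_layout(config)
    phi = config.nb_dispersion

    gene_ids = [g.gene_id for g in genes]
    mirna_ids = [m.id for m in mirnas]

    n_targeting = {g: 0 for g in gene_ids}
    for m, sites in truth.target_map.items():
        if m in truth.up_mirna_ids:
            for g, _ in sites:
                n_targeting[g] += 1

    def baselines(n: int, log_mean: tuple[float, float]) -> np.ndarray:
        b = np.exp(rng.normal(log_mean[0], log_mean[1], size=n))
        return np.maximum(b, config.baseline_mean_floor)

    # Planted features (changed miRNAs, targeted genes) sit at moderate,
    # power-sufficient abundance; the bulk carries most of the library mass
    # (as in real small-RNA libraries, dominated by a few abundant species)
    # so the planted fold changes barely perturb column totals.
    base_g = baselines(len(gene_ids), config.baseline_log_mean)
    base_m = baselines(len(mirna_ids), config.mirna_baseline_log_mean)
    plo, phi_b = config.planted_baseline_range
    for i, g in enumerate(gene_ids):
        if n_targeting[g] > 0:
            base_g[i] = rng.uniform(plo, phi_b)
    for i, m in enumerate(mirna_ids):
        if m in truth.up_mirna_ids or m in truth.down_mirna_ids:
            base_m[i] = rng.uniform(plo, phi_b)

    # Constant (shared across pairs) planted tumor effects.
    gene_effect = np.ones(len(gene_ids))
    for i, g in enumerate(gene_ids):
        if n_targeting[g] > 0:
            gene_effect[i] = max(
                config.target_suppression_fc ** n_targeting[g], config.suppression_floor
            )
    mirna_effect = np.ones(len(mirna_ids))
    for i, m in enumerate(mirna_ids):
        if m in truth.up_mirna_ids:
            mirna_effect[i] = config.planted_mirna_fc
        elif m in truth.down_mirna_ids:
            mirna_effect[i] = 1.0 / config.planted_mirna_fc

    # Background DE: per-feature-per-pair log-normal fold changes on a random
    # subset of the unplanted features.
    planted_g = {i for i, g in enumerate(gene_ids) if n_targeting[g] > 0}
    planted_m = {
        i
        for i, m in enumerate(mirna_ids)
        if m in truth.up_mirna_ids or m in truth.down_mirna_ids
    }

    def background(n: int, planted: set[int]) -> dict[int, np.ndarray]:
        eligible = np.array([i for i in range(n) if i not in planted])
        k = int(round(config.background_de_fraction * n))
        k = min(k, len(eligible))
        if k == 0:
            return {}
        chosen = rng.choice(eligible, size=k, replace=False)
        fcs = 2.0 ** rng.normal(0.0, config.background_log2fc_sd, size=(k, config.n_pairs))
        return {int(i): fcs[j] for j, i in enumerate(chosen)}

    bg_g = background(len(gene_ids), planted_g)
    bg_m = background(len(mirna_ids), planted_m)

    lo, hi = config.library_size_range

    def draw_matrix(base: np.ndarray, effect: np.ndarray, bg: dict[int, np.ndarray]):
        libs = rng.integers(lo, hi + 1, size=len(sample_ids))
        total_base = base.sum()
        counts = np.zeros((len(base), len(sample_ids)), dtype=np.int64)
        effects_by_pair: list[np.ndarray] = []
        for pi in range(config.n_pairs):
            eff = effect.copy()
            for i, fcs in bg.items():
                eff[i] *= fcs[pi]
            effects_by_pair.append(eff)
        for j, sid in enumerate(sample_ids):
            pi = j // 2
            eff = effects_by_pair[pi] if conditions[j] == "tumor" else np.ones(len(base))
            mean = base * eff * (libs[j] / total_base)
            if phi == 0.0:
                counts[:, j] = rng.poisson(mean)
            else:
                lam = rng.gamma(shape=1.0 / phi, scale=phi * mean)
                counts[:, j] = rng.poisson(lam)
        return counts, libs, effects_by_pair

    counts_g, libs_g, eff_g = draw_matrix(base_g, gene_effect, bg_g)
    counts_m, libs_m, eff_m = draw_matrix(base_m, mirna_effect, bg_m)

    truth.per_pair_effects = {}
    for pi, pair in enumerate(pairs):
        d: dict[str, float] = {}
        for i, g in enumerate(gene_ids):
            if eff_g[pi][i] != 1.0:
                d[g] = float(eff_g[pi][i])
        for i, m in enumerate(mirna_ids):
            if eff_m[pi][i] != 1.0:
                d[m] = float(eff_m[pi][i])
        truth.per_pair_effects[pair] = d

    def metadata(counts: np.ndarray, rate_range: tuple[float, float]) -> pd.DataFrame:
        colsums = counts.sum(axis=0)
        rates = rng.uniform(*rate_range, size=len(sample_ids))
        return pd.DataFrame(
            {
                "pair_id": [p for p in pairs for _ in range(2)],
                "condition": conditions,
                "total_clean_reads": np.ceil(colsums / rates).astype(int),
                "uniquely_mapped_reads": colsums,
            },
            index=sample_ids,
        )

    meta_g = metadata(counts_g, (0.6, 0.75))
    meta_m = metadata(counts_m, (0.2, 0.5))

    mrna_cm = CountMatrix(
        pd.DataFrame(counts_g, index=gene_ids, columns=sample_ids),
        meta_g,
        feature_lengths=pd.Series(
            [g.exonic_length for g in genes], index=gene_ids, name="length_nt"
        ),
    )
    mirna_cm = CountMatrix(
        pd.DataFrame(counts_m, index=mirna_ids, columns=sample_ids), meta_m
    )
    return mrna_cm, mirna_cm


def generate_cohort(
    config: SimulationConfig,
) -> tuple[list[GeneRecord], list[MiRNARecord], CountMatrix, CountMatrix, SyntheticTruth]:
    """Run all generation stages: transcriptome, mirnome, planting, counts."""
    genes = generate_transcriptome(config)
    mirnas = generate_mirnome(config)
    genes, truth = plant_target_sites(genes, mirnas, config)
    mrna_cm, mirna_cm = simulate_counts(genes, mirnas, truth, config)
    return genes, mirnas, mrna_cm, mirna_cm, truth


def write_cohort(
    genes: list[GeneRecord],
    mirnas: list[MiRNARecord],
    mrna_counts: CountMatrix,
    mirna_counts: CountMatrix,
    truth: SyntheticTruth,
    outdir,
) -> dict[str, Path]:
    """Write the full cohort as plain-text artifacts; returns the file map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {
        "utr_fasta": outdir / "utrs.fasta",
        "mirna_fasta": outdir / "mirnas.fasta",
        "mrna_counts": outdir / "mrna_counts.tsv",
        "mrna_lengths": outdir / "mrna_lengths.tsv",
        "mirna_counts": outdir / "mirna_counts.tsv",
        "tf_list": outdir / "tf_list.tsv",
        "go_map": outdir / "go_map.gmt",
        "truth": outdir / "truth.json",
    }
    mio.write_fasta({g.gene_id: g.utr_seq for g in genes}, files["utr_fasta"])
    mio.write_fasta({m.id: m.mature_seq for m in mirnas}, files["mirna_fasta"])
    mio.write_counts(mrna_counts, files["mrna_counts"], lengths_path=files["mrna_lengths"])
    mio.write_counts(mirna_counts, files["mirna_counts"])
    mio.write_tf_list([g.gene_id for g in genes if g.is_tf], files["tf_list"])
    terms: dict[str, tuple[str, set[str]]] = {}
    for g in genes:
        for t in g.go_terms:
            name = TF_TERM_NAME if t == TF_TERM_ID else f"synthetic process {t[-7:]}"
            terms.setdefault(t, (name, set()))[1].add(g.gene_id)
    mio.write_gmt(terms, files["go_map"])
    files["truth"].write_text(truth.to_json())
    return files


def read_truth(path) -> SyntheticTruth:
    return SyntheticTruth.from_json(Path(path).read_text())
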