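"""Synthetic data generation with planted ground truth.

Every input the analysis stages consume can be generated here: replicate
growth curves with a planted combination index, three correlated
differential-expression studies whose log2 fold-changes shift with the
number of targeting miRNAs and binding sites, miRNA-family target sets with
planted cluster structure, transcript sequences with planted seed sites (and
no accidental ones), and a survival cohort whose hazard depends on a planted
average-z-score effect.

One global seed expands into independent per-stream child seeds, so adding a
generator never perturbs existing streams, and identical config + seed gives
byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .sites import (
    DEFAULT_SITE_TYPES,
    normalize_sequence,
    reverse_complement,
    scan_sites,
)

MIRNAS = ("miR-124", "miR-128", "miR-137")

# Mature guide-strand sequences (5'->3') of the three proneurogenic miRNAs.
MIRNA_SEQUENCES = {
    "miR-124": "UAAGGCACGCGGUGAAUGCC",
    "miR-128": "UCACAGUGAACCGGUCUCUUU",
    "miR-137": "UUAUUGCUUAAGAAUACGCGUAG",
}

# Fixed child-stream identifiers: appending new streams never shifts old ones.
_STREAMS = {
    "growth": 11,
    "de": 23,
    "families": 37,
    "sequences": 41,
    "survival": 53,
    "biased_targets": 67,
}


class SynthConfigError(ValueError):
    """A synthetic-data configuration violates a stated bound."""


@dataclass
class SynthConfig:
    """All knobs of the synthetic-data generator.

    Defaults emulate the study conditions: three biological replicates imaged
    to a 120 h endpoint, a strongly synergistic planted combination index,
    three transfection studies of a few thousand genes with ~25% of genes
    targeted per miRNA, six miRNA families in two planted groups, and a
    300-patient cohort with 20% censoring.
    """

    seed: int = 0

    # growth curves
    n_timepoints: int = 25
    t_max_h: float = 120.0
    n_replicates: int = 3
    noise_cv: float = 0.05
    # per-observation measurement jitter CV; defaults to 0.2 * noise_cv
    obs_noise_cv: float | None = None
    planted_ci: float = 0.35
    single_effects: tuple[float, float, float] = (0.08, 0.10, 0.12)

    # differential-expression studies
    n_genes: int = 5000
    frac_targeted: float = 0.25
    delta_per_mirna: float = -0.3
    delta_per_site: float = -0.15
    lfc_sigma_shared: float = 0.30
    lfc_sigma_study: float = 0.25
    frac_lncrna: float = 0.10
    padj_rate: float = 8.0
    padj_jitter: float = 0.30

    # survival cohort
    n_patients: int = 300
    hazard_beta: float = -math.log(2.0)  # protective: high score, longer survival
    censor_rate: float = 0.20
    expr_corr: float = 0.5
    baseline_median_months: float = 24.0

    # family target sets
    n_families: int = 6
    family_group_sizes: tuple[int, ...] = (3, 3)
    targets_per_family: int = 150
    within_overlap: float = 0.8
    between_overlap: float = 0.1

    # sequences with planted seed sites
    n_sequences: int = 30
    seq_length: int = 300
    fraction_triple: float = 0.5
    nontriple_site_prob: float = 0.5
    max_sites_per_mirna: int = 2

    def validate(self) -> None:
        if self.planted_ci <= 0:
            raise SynthConfigError(f"planted_ci must be > 0, got {self.planted_ci}")
        for e in self.single_effects:
            if not 0 <= e < 1:
                raise SynthConfigError(
                    f"single_effects must lie in [0, 1), got {e}"
                )
        e_combo = sum(self.single_effects) / self.planted_ci
        if not e_combo < 1:
            raise SynthConfigError(
                "sum(single_effects)/planted_ci must be < 1 for a valid "
                f"combination effect, got {e_combo:.3f}"
            )
        if self.noise_cv < 0:
            raise SynthConfigError(f"noise_cv must be >= 0, got {self.noise_cv}")
        if not 0 < self.frac_targeted < 1:
            raise SynthConfigError(
                f"frac_targeted must be in (0, 1), got {self.frac_targeted}"
            )
        if sum(self.family_group_sizes) != self.n_families:
            raise SynthConfigError(
                f"family_group_sizes {self.family_group_sizes} must sum to "
                f"n_families={self.n_families}"
            )
        if self.within_overlap <= self.between_overlap:
            raise SynthConfigError(
                "within_overlap must exceed between_overlap "
                f"({self.within_overlap} <= {self.between_overlap}): planted "
                "structure unrecoverable"
            )
        if not math.isfinite(self.hazard_beta):
            raise SynthConfigError("hazard_beta must be finite")
        if not 0 <= self.censor_rate < 1:
            raise SynthConfigError(
                f"censor_rate must be in [0, 1), got {self.censor_rate}"
            )
        min_len = 10 * (1 + 3 * self.max_sites_per_mirna)
        if self.seq_length < min_len:
            raise SynthConfigError(
                f"seq_length={self.seq_length} too short to host up to "
                f"{self.max_sites_per_mirna} sites per miRNA (need >= {min_len})"
            )

    @classmethod
    def from_dict(cls, d: Mapping) -> "SynthConfig":
        d = dict(d)
        for key in ("single_effects", "family_group_sizes"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return asdict(self)


def _rng(cfg_seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[stream], cfg_seed])


# ---------------------------------------------------------------------------
# growth curves


def gen_growth_curves(cfg: SynthConfig) -> pd.DataFrame:
    """Logistic confluence trajectories for control, A, B, C and ABC arms.

    Arm X reaches an endpoint signal of ``control * (1 - E_X)``; the
    combination effect is planted as ``sum(single_effects) / planted_ci`` so
    the linear-interaction combination index of the noise-free curves equals
    ``planted_ci`` exactly.

    Noise has two multiplicative log-normal components, mirroring a paired
    live-cell imaging design in which each biological replicate is one
    transfection batch carrying every arm alongside its own control:
    a per-replicate batch factor with CV ``noise_cv`` shared by all arms and
    timepoints of that replicate (seeding density, plate effects), and an
    independent per-observation measurement jitter with CV ``obs_noise_cv``
    (0.2 * noise_cv unless set). The batch factor dominates raw signal
    spread but largely cancels in arm/control ratios.
    """
    cfg.validate()
    rng = _rng(cfg.seed, "growth")
    t = np.linspace(0.0, cfg.t_max_h, cfg.n_timepoints)
    s0, cap = 5.0, 95.0
    rate = 0.05
    control = cap / (1.0 + (cap - s0) / s0 * np.exp(-rate * t))

    e_abc = sum(cfg.single_effects) / cfg.planted_ci
    effects = {
        "control": 0.0,
        "A": cfg.single_effects[0],
        "B": cfg.single_effects[1],
        "C": cfg.single_effects[2],
        "ABC": e_abc,
    }

    def sigma_of(cv: float) -> float:
        return math.sqrt(math.log(1.0 + cv**2)) if cv > 0 else 0.0

    sigma_batch = sigma_of(cfg.noise_cv)
    obs_cv = 0.2 * cfg.noise_cv if cfg.obs_noise_cv is None else cfg.obs_noise_cv
    sigma_obs = sigma_of(obs_cv)

    batch = (
        rng.lognormal(-0.5 * sigma_batch**2, sigma_batch, cfg.n_replicates)
        if sigma_batch > 0
        else np.ones(cfg.n_replicates)
    )
    ramp = t / cfg.t_max_h  # effect builds linearly to the endpoint
    rows = []
    for arm, e in effects.items():
        mean_traj = control * (1.0 - e * ramp)
        for rep in range(1, cfg.n_replicates + 1):
            if sigma_obs > 0:
                jitter = rng.lognormal(-0.5 * sigma_obs**2, sigma_obs, t.size)
            else:
                jitter = np.ones_like(t)
            rows.append(
                pd.DataFrame(
                    {
                        "arm": arm,
                        "replicate": rep,
                        "time_h": t,
                        "signal": mean_traj * batch[rep - 1] * jitter,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# differential-expression studies


def gen_de_studies(
    cfg: SynthConfig,
) -> tuple[list[pd.DataFrame], pd.DataFrame, pd.DataFrame]:
    """Three correlated DE study tables, a target map, and ground truth.

    Each gene is targeted independently by each of the three miRNAs with
    probability ``frac_targeted``; each (gene, miRNA) pair carries 1-3
    binding sites. The planted log2FC shift is
    ``delta_per_mirna * n_mirnas + delta_per_site * (total_sites - n_mirnas)``
    (one site per targeting miRNA is "free"; extra sites add burden).
    Adjusted p-values are a monotone transform of |log2FC| with jitter.
    """
    cfg.validate()
    rng = _rng(cfg.seed, "de")
    n = cfg.n_genes
    gene_ids = np.array([f"G{i:06d}" for i in range(n)])
    biotype = np.where(
        rng.random(n) < cfg.frac_lncrna, "lncRNA", "protein_coding"
    )

    targeted = rng.random((n, 3)) < cfg.frac_targeted  # gene x miRNA
    site_counts = np.where(targeted, rng.integers(1, 4, size=(n, 3)), 0)
    n_mirnas = targeted.sum(axis=1)
    total_sites = site_counts.sum(axis=1)
    extra_sites = total_sites - n_mirnas
    true_shift = cfg.delta_per_mirna * n_mirnas + cfg.delta_per_site * extra_sites

    shared = true_shift + rng.normal(0.0, cfg.lfc_sigma_shared, size=n)
    studies = []
    for study in ("study1", "study2", "study3"):
        lfc = shared + rng.normal(0.0, cfg.lfc_sigma_study, size=n)
        raw = np.exp(-cfg.padj_rate * np.abs(lfc))
        jitter = np.exp(rng.normal(0.0, cfg.padj_jitter, size=n))
        padj = np.minimum(1.0, raw * jitter)
        studies.append(
            pd.DataFrame(
                {
                    "study": study,
                    "gene_id": gene_ids,
                    "biotype": biotype,
                    "log2fc": lfc,
                    "padj": padj,
                }
            )
        )

    gi, mi = np.nonzero(targeted)
    target_map = pd.DataFrame(
        {
            "gene_id": gene_ids[gi],
            "mirna": np.array(MIRNAS)[mi],
            "site_count": site_counts[gi, mi],
        }
    )
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "biotype": biotype,
            "n_mirnas": n_mirnas,
            "total_sites": total_sites,
            "true_shift": true_shift,
        }
    )
    return studies, target_map, truth


def gen_biased_target_map(
    gene_ids: Sequence[str],
    favored: set[str],
    *,
    base_rate: float = 0.25,
    odds_ratio: float = 3.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Target map where favoured genes are targeted at ``odds_ratio`` : 1 odds.

    Each of the three miRNAs targets a background gene with probability
    ``base_rate``; for favoured genes the targeting odds are multiplied by
    ``odds_ratio``. Used to plant (or, with odds_ratio=1, null out) target
    enrichment in a gene set.
    """
    if not 0 < base_rate < 1:
        raise SynthConfigError(f"base_rate must be in (0, 1), got {base_rate}")
    rng = _rng(seed, "biased_targets")
    # sorted order so results do not depend on set/dict iteration order
    ids = np.asarray(sorted(str(g) for g in gene_ids))
    odds = base_rate / (1.0 - base_rate) * odds_ratio
    p_fav = odds / (1.0 + odds)
    is_fav = np.isin(ids, list(favored))
    p = np.where(is_fav, p_fav, base_rate)
    hit = rng.random((ids.size, 3)) < p[:, None]
    gi, mi = np.nonzero(hit)
    return pd.DataFrame(
        {
            "gene_id": ids[gi],
            "mirna": np.array(MIRNAS)[mi],
            "site_count": 1,
        }
    )


# ---------------------------------------------------------------------------
# family target sets


def gen_family_targets(cfg: SynthConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """miRNA-family target sets with planted group structure.

    Families in the same planted group share ``within_overlap`` of their
    targets (a group core); all families share ``between_overlap`` (a
    universal core), so cross-group overlap is ``between_overlap``. Cores and
    private targets are drawn from disjoint gene pools, making the planted
    overlaps exact up to rounding.
    """
    cfg.validate()
    t = cfg.targets_per_family
    n_universal = round(cfg.between_overlap * t)
    n_group = round(cfg.within_overlap * t) - n_universal
    n_private = t - n_universal - n_group
    if n_private < 0:
        raise SynthConfigError("within_overlap rounds above 1.0")

    counter = 0

    def take(k: int) -> list[str]:
        nonlocal counter
        out = [f"T{counter + i:06d}" for i in range(k)]
        counter += k
        return out

    universal = take(n_universal)
    rows, truth_rows = [], []
    fam_idx = 0
    for group, size in enumerate(cfg.family_group_sizes):
        group_core = take(n_group)
        for _ in range(size):
            fam = f"family{fam_idx + 1:02d}"
            targets = universal + group_core + take(n_private)
            rows.extend({"family": fam, "gene_id": g} for g in targets)
            truth_rows.append({"family": fam, "group": group})
            fam_idx += 1
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# sequences with planted seed sites


def _random_clean_sequence(
    rng: np.random.Generator, length: int, forbidden: Sequence[str]
) -> str:
    """Random sequence containing none of the forbidden 6mer cores."""
    bases = np.array(list("ACGT"))
    for _ in range(1000):
        seq = "".join(rng.choice(bases, size=length))
        if not any(core in seq for core in forbidden):
            return seq
    raise RuntimeError("rejection sampling failed to produce a clean sequence")


def _site_insert(mirna_seq: str, site_type: str, rng: np.random.Generator) -> str:
    """The target-strand string realising one canonical site."""
    m = normalize_sequence(mirna_seq, name="miRNA")
    rc7 = reverse_complement(m[1:8])  # m8 match + 6mer core
    core = rc7[1:]
    if site_type == "8mer":
        return rc7 + "A"
    if site_type == "7mer-m8":
        return rc7 + str(rng.choice(["C", "G", "T"]))
    if site_type == "7mer-A1":
        not_m8 = [b for b in "ACGT" if b != rc7[0]]
        return str(rng.choice(not_m8)) + core + "A"
    raise ValueError(f"cannot plant site type {site_type!r}")


def gen_sequences(
    cfg: SynthConfig,
    mirnas: Mapping[str, str] | None = None,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Random sequences with planted canonical sites and clean background.

    A ``fraction_triple`` share of sequences carries at least one site for
    every miRNA; the rest carry sites for a random subset of miRNAs (each
    included with probability ``nontriple_site_prob``). Background is
    rejection-sampled to contain no unplanned 6mer seed core, and each
    planted sequence is re-scanned and regenerated until the scan output
    equals the planted table exactly, so scanner false positives and
    negatives are zero by construction.

    Returns the id->sequence dict and the planted-site table
    (sequence_id, mirna, site_type, start, end).
    """
    cfg.validate()
    if mirnas is None:
        mirnas = MIRNA_SEQUENCES
    norm = {k: normalize_sequence(v, name=k) for k, v in mirnas.items()}
    for k, v in norm.items():
        if len(v) < 8:
            raise SynthConfigError(f"miRNA {k} shorter than 8 nt")
    forbidden = [reverse_complement(v[1:7]) for v in norm.values()]
    rng = _rng(cfg.seed, "sequences")
    names = list(norm)

    n_triple = round(cfg.fraction_triple * cfg.n_sequences)
    triple_flags = np.zeros(cfg.n_sequences, dtype=bool)
    triple_flags[
        rng.choice(cfg.n_sequences, size=n_triple, replace=False)
    ] = True

    seqs: dict[str, str] = {}
    planted_rows = []
    for idx in range(cfg.n_sequences):
        seq_id = f"lnc{idx + 1:04d}"
        if triple_flags[idx]:
            chosen = list(names)
        else:
            # at most 2 miRNAs, so only flagged sequences are triple-targeted
            k = min(int((rng.random(len(names)) < cfg.nontriple_site_prob).sum()), 2)
            chosen = [names[i] for i in rng.choice(len(names), size=k, replace=False)]
        plan = []  # (mirna, site_type) to plant
        for m in chosen:
            k = int(rng.integers(1, cfg.max_sites_per_mirna + 1))
            for _ in range(k):
                plan.append((m, str(rng.choice(DEFAULT_SITE_TYPES))))

        for _attempt in range(200):
            seq = _random_clean_sequence(rng, cfg.seq_length, forbidden)
            slots = np.arange(1, cfg.seq_length - 10, 12)
            if len(plan) > slots.size:
                raise SynthConfigError(
                    f"seq_length={cfg.seq_length} too short for "
                    f"{len(plan)} planted sites"
                )
            starts = np.sort(rng.choice(slots, size=len(plan), replace=False))
            order = rng.permutation(len(plan))
            rows = []
            chars = list(seq)
            ok = True
            for slot_start, j in zip(starts, order):
                m, site_type = plan[j]
                ins = _site_insert(norm[m], site_type, rng)
                chars[slot_start : slot_start + len(ins)] = list(ins)
                if site_type == "7mer-A1":
                    start, end = slot_start + 1, slot_start + 8
                elif site_type == "8mer":
                    start, end = slot_start, slot_start + 8
                else:  # 7mer-m8: first 7 inserted chars, trailing base is filler
                    start, end = slot_start, slot_start + 7
                rows.append(
                    {
                        "sequence_id": seq_id,
                        "mirna": m,
                        "site_type": site_type,
                        "start": start,
                        "end": end,
                    }
                )
            candidate = "".join(chars)
            # verify: the scan must recover exactly the planted sites
            found = set()
            for m in names:
                for s in scan_sites(
                    norm[m], candidate, mirna=m, sequence_id=seq_id
                ):
                    found.add((m, s.site_type, s.start, s.end))
            planted = {
                (r["mirna"], r["site_type"], r["start"], r["end"]) for r in rows
            }
            if found == planted:
                seqs[seq_id] = candidate
                planted_rows.extend(rows)
                ok = True
                break
            ok = False
        if not ok:
            raise RuntimeError(f"could not plant sites cleanly in {seq_id}")

    planted_df = pd.DataFrame(
        planted_rows, columns=["sequence_id", "mirna", "site_type", "start", "end"]
    )
    return seqs, planted_df


def triple_ground_truth(planted: pd.DataFrame, n_mirnas: int = 3) -> list[str]:
    """Sequence ids whose planted sites cover all miRNAs."""
    if planted.empty:
        return []
    per_seq = planted.groupby("sequence_id")["mirna"].nunique()
    return sorted(per_seq.index[per_seq == n_mirnas])


# ---------------------------------------------------------------------------
# survival cohort


def gen_survival_cohort(cfg: SynthConfig) -> pd.DataFrame:
    """Patient cohort with correlated miRNA expression and planted hazard.

    Expression of the three miRNAs is multivariate standard normal with
    pairwise correlation ``expr_corr``. Event times are exponential with
    rate ``lambda0 * exp(hazard_beta * avg_z)`` where ``avg_z`` is the
    per-patient mean expression; censoring is independent exponential tuned
    to ``censor_rate``.
    """
    cfg.validate()
    rng = _rng(cfg.seed, "survival")
    n = cfg.n_patients
    cov = np.full((3, 3), cfg.expr_corr)
    np.fill_diagonal(cov, 1.0)
    expr = rng.multivariate_normal(np.zeros(3), cov, size=n, method="cholesky")
    avg_z = expr.mean(axis=1)

    lam0 = math.log(2.0) / cfg.baseline_median_months
    lam = lam0 * np.exp(cfg.hazard_beta * avg_z)
    event_time = rng.exponential(1.0 / lam)
    if cfg.censor_rate > 0:
        lam_c = lam0 * cfg.censor_rate / (1.0 - cfg.censor_rate)
        censor_time = rng.exponential(1.0 / lam_c, size=n)
    else:
        censor_time = np.full(n, np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    return pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(n)],
            "miR-124": expr[:, 0],
            "miR-128": expr[:, 1],
            "miR-137": expr[:, 2],
            "time": time,
            "event": event,
        }
    )


# ---------------------------------------------------------------------------
# file output


def write_fasta(seqs: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_all(cfg: SynthConfig, outdir) -> dict[str, str]:
    """Generate every synthetic input and write it under ``outdir``.

    Returns a mapping of artifact name to file path. Ground-truth tables
    (planted sites, family groups, gene-level planting) are written
    alongside the inputs.
    """
    cfg.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def save(name: str, df: pd.DataFrame, fname: str) -> None:
        p = out / fname
        df.to_csv(p, sep="\t", index=False, float_format="%.10g")
        paths[name] = str(p)

    save("growth_curves", gen_growth_curves(cfg), "growth_curves.tsv")

    studies, target_map, truth = gen_de_studies(cfg)
    for s in studies:
        name = s["study"].iloc[0]
        save(f"de_{name}", s, f"de_{name}.tsv")
    save("target_map", target_map, "target_map.tsv")
    save("de_ground_truth", truth, "de_ground_truth.tsv")

    fam, fam_truth = gen_family_targets(cfg)
    save("family_targets", fam, "family_targets.tsv")
    save("family_ground_truth", fam_truth, "family_ground_truth.tsv")

    seqs, planted = gen_sequences(cfg)
    fasta = out / "sequences.fasta"
    write_fasta(seqs, fasta)
    paths["sequences"] = str(fasta)
    save("planted_sites", planted, "planted_sites.tsv")

    save("survival_cohort", gen_survival_cohort(cfg), "survival_cohort.tsv")

    with open(out / "synth_config.yaml", "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
    paths["config"] = str(out / "synth_config.yaml")
    return paths
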