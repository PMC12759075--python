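"""Ground-truth LiP-MS experiment simulator.

Generates a random proteome, a LiP (PK + trypsin) ion table, a matched
trypsin-only control table, a study design and the truth labels needed to
benchmark the inference chain end to end: which proteins carry perturbed
cut-sites, with what fold effects, and which proteins shifted in
abundance between conditions.

The emulated statistical structure: fully tryptic and half-tryptic ions
(about 55% of LiP ions half-tryptic, about 10% in controls), three
biological replicates per condition by default, log-normal replicate
noise, Bernoulli detection, condition-exclusive ions at designated
perturbed sites (producing the "lobes" of a peptide volcano plot after
imputation), and protein-level abundance rebalancing between strains.

Randomness comes from a single root seed with named substreams per stage,
so any stage is reproducible in isolation.  Counts derived from fractions
use round-half-up, making truth sizes exact.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .peptide_map import AMINO_ACIDS, ProteinSeq, digest_tryptic
from .differential import SampleInfo, StudyDesign, TREATMENT_CONTROL, TREATMENT_LIP

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimDataset",
    "simulate_proteome",
    "simulate_experiment",
    "simulate_annotations",
    "simulate_dataset",
    "write_fixture",
]

ION_KEY_COLUMNS = ["protein_id", "peptide", "charge", "mod_key", "start", "end"]

# substream indices for the per-stage RNGs
_STAGES = {
    "proteome": 0,
    "truth": 1,
    "abundance": 2,
    "ions": 3,
    "noise": 4,
    "detection": 5,
    "annotation": 6,
}

_COFACTOR_VOCAB = (
    "heme", "PLP", "[4Fe-4S]", "[3Fe-4S]", "[2Fe-2S]", "Zn2+", "FAD", "THDP",
)
_XGROUP_VOCAB = (
    "Rossmann", "TIM-barrel", "beta-propeller", "OB-fold", "ferredoxin-like",
    "alpha-helical-bundle", "SH3-like", "jelly-roll", "P-loop-NTPase",
    "immunoglobulin-like", "beta-grasp", "flavodoxin-like",
)


def round_half_up(x: float) -> int:
    """Deterministic fraction-to-count rule used throughout the simulator."""
    return int(math.floor(x + 0.5))


class SimConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a simulated LiP-MS experiment.

    Defaults mirror a typical knockout-vs-wild-type design: three
    biological replicates, ~20% log-normal replicate noise, ~55%
    half-tryptic ions in LiP samples and ~10% in trypsin-only controls,
    and four-fold effects at designated perturbed sites.
    """

    n_proteins: int = 100
    protein_length_range: tuple[int, int] = (150, 400)
    replicates: int = 3
    cv: float = 0.2
    frac_perturbed_proteins: float = 0.1
    sites_per_perturbed_protein: tuple[int, int] = (2, 4)
    site_effect_fold: float = 4.0
    exclusive_site_prob: float = 0.3
    frac_abundance_shifted: float = 0.1
    abundance_fold_range: tuple[float, float] = (1.5, 4.0)
    detection_prob: float = 0.95
    half_tryptic_target_frac: float = 0.55
    control_half_tryptic_frac: float = 0.10
    test_condition: str = "ko"
    reference_condition: str = "wt"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise SimConfigError("n_proteins must be >= 1")
        lo, hi = self.protein_length_range
        if not (30 <= lo <= hi):
            raise SimConfigError(
                "protein_length_range must satisfy 30 <= min <= max "
                "(shorter proteins cannot guarantee three tryptic peptides)"
            )
        if self.replicates < 2:
            raise SimConfigError("replicates must be >= 2")
        for name in (
            "frac_perturbed_proteins", "frac_abundance_shifted",
            "detection_prob", "half_tryptic_target_frac",
            "control_half_tryptic_frac", "exclusive_site_prob",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise SimConfigError(f"{name} must be in [0, 1]")
        if self.cv < 0:
            raise SimConfigError("cv must be >= 0")
        if self.site_effect_fold <= 0:
            raise SimConfigError("site_effect_fold must be > 0")
        if min(self.abundance_fold_range) <= 0:
            raise SimConfigError("abundance folds must be > 0")
        k_lo, k_hi = self.sites_per_perturbed_protein
        if not (1 <= k_lo <= k_hi):
            raise SimConfigError("sites_per_perturbed_protein must be ordered, >= 1")
        if not 0 <= self.seed < 2**31:
            raise SimConfigError("seed must lie in [0, 2**31)")


def _rng(cfg: SimConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, _STAGES[stage]])


@dataclass
class SimTruth:
    """Ground truth emitted by the generator.

    ``perturbed_sites`` maps protein id to a list of site records
    ``{"position": int, "fold": float | None, "exclusive": bool}``; an
    exclusive site has no detectable half-tryptic ion in the reference
    condition (fold undefined).  ``abundance_multipliers`` holds the
    test-condition abundance factor for every rebalanced protein.
    """

    perturbed_proteins: list[str] = field(default_factory=list)
    perturbed_sites: dict[str, list[dict]] = field(default_factory=dict)
    abundance_multipliers: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if set(self.perturbed_sites) - set(self.perturbed_proteins):
            raise ValueError("perturbed_sites keys must be perturbed proteins")
        for pid, sites in self.perturbed_sites.items():
            for s in sites:
                if not isinstance(s.get("position"), int):
                    raise ValueError(f"{pid}: site position must be an int")
                if not isinstance(s.get("exclusive"), bool):
                    raise ValueError(f"{pid}: exclusive flag must be a bool")
                fold = s.get("fold")
                if fold is not None and not fold > 0:
                    raise ValueError(f"{pid}: site fold must be positive")

    def to_json(self) -> str:
        self.validate()
        return json.dumps(
            {
                "perturbed_proteins": sorted(self.perturbed_proteins),
                "perturbed_sites": {
                    k: self.perturbed_sites[k] for k in sorted(self.perturbed_sites)
                },
                "abundance_multipliers": {
                    k: self.abundance_multipliers[k]
                    for k in sorted(self.abundance_multipliers)
                },
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        d = json.loads(text)
        truth = cls(
            perturbed_proteins=list(d["perturbed_proteins"]),
            perturbed_sites={k: list(v) for k, v in d["perturbed_sites"].items()},
            abundance_multipliers={
                k: float(v) for k, v in d["abundance_multipliers"].items()
            },
        )
        truth.validate()
        return truth


def simulate_proteome(cfg: SimConfig) -> list[ProteinSeq]:
    """Random protein sequences with uniform residue frequencies.

    Each protein is rejection-sampled until its tryptic digest yields at
    least three peptides of length >= 6, which guarantees the experiment
    generator can always place both tryptic and half-tryptic ions.
    """
    rng = _rng(cfg, "proteome")
    lo, hi = cfg.protein_length_range
    width = max(4, len(str(cfg.n_proteins)))
    alphabet = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1")
    proteins: list[ProteinSeq] = []
    for i in range(cfg.n_proteins):
        pid = f"P{i + 1:0{width}d}"
        for attempt in range(10_000):
            length = int(rng.integers(lo, hi + 1))
            seq = b"".join(
                alphabet[rng.integers(0, len(alphabet), size=length)]
            ).decode()
            protein = ProteinSeq(pid, seq)
            spans = digest_tryptic(protein)
            if sum(1 for s in spans if s.end - s.start + 1 >= 6) >= 3:
                proteins.append(protein)
                break
        else:
            raise SimConfigError(
                f"could not satisfy digest constraints at length range {lo}-{hi}"
            )
    return proteins


def _make_design(cfg: SimConfig) -> StudyDesign:
    samples = []
    for cond in (cfg.test_condition, cfg.reference_condition):
        for treat, tag in ((TREATMENT_LIP, "lip"), (TREATMENT_CONTROL, "ctl")):
            for rep in range(1, cfg.replicates + 1):
                samples.append(
                    SampleInfo(f"{cond}_{tag}_{rep}", cond, treat, rep)
                )
    return StudyDesign(
        tuple(samples), (cfg.test_condition, cfg.reference_condition)
    )


@dataclass
class SimDataset:
    """Everything one simulated experiment produces."""

    config: SimConfig
    proteome: list[ProteinSeq]
    lip_ions: pd.DataFrame
    control_ions: pd.DataFrame
    design: StudyDesign
    truth: SimTruth
    annotations: pd.DataFrame
    #: per-LiP-ion provenance: half-tryptic ions carry their true PK cut position
    lip_provenance: pd.DataFrame


def simulate_experiment(
    proteome: list[ProteinSeq], cfg: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame, StudyDesign, SimTruth, pd.DataFrame]:
    """Simulate LiP and trypsin-only ion tables over a proteome.

    Returns ``(lip_ions, control_ions, design, truth, lip_provenance)``.
    ``lip_provenance`` records, for every LiP ion row, whether it is
    half-tryptic and the PK cut position it was generated from.
    """
    truth_rng = _rng(cfg, "truth")
    abundance_rng = _rng(cfg, "abundance")
    ion_rng = _rng(cfg, "ions")
    design = _make_design(cfg)

    n = len(proteome)
    ids = [p.id for p in proteome]
    n_pert = round_half_up(cfg.frac_perturbed_proteins * n)
    n_shift = round_half_up(cfg.frac_abundance_shifted * n)
    perturbed = sorted(truth_rng.choice(ids, size=n_pert, replace=False).tolist())
    shifted = sorted(truth_rng.choice(ids, size=n_shift, replace=False).tolist())

    truth = SimTruth(perturbed_proteins=list(perturbed))
    fold_lo, fold_hi = cfg.abundance_fold_range
    for pid in shifted:
        fold = float(abundance_rng.uniform(fold_lo, fold_hi))
        if abundance_rng.random() < 0.5:
            fold = 1.0 / fold
        truth.abundance_multipliers[pid] = fold

    frac = cfg.half_tryptic_target_frac
    ctl_frac = cfg.control_half_tryptic_frac
    k_lo, k_hi = cfg.sites_per_perturbed_protein

    # per-ion base intensities in each condition (pre-noise, pre-detection)
    lip_rows: list[dict] = []
    ctl_rows: list[dict] = []
    lip_prov: list[dict] = []

    for protein in proteome:
        pid = protein.id
        base = 10.0 ** abundance_rng.uniform(6.0, 9.0)
        mult = truth.abundance_multipliers.get(pid, 1.0)
        spans = [
            s for s in digest_tryptic(protein) if (s.end - s.start + 1) >= 4
        ]
        responses = 10.0 ** ion_rng.uniform(-2.0, 0.0, size=len(spans))
        full_int = {s: base * r for s, r in zip(spans, responses)}

        # choose PK cut positions inside tryptic peptides; position 1 on a
        # Met-initiated protein is skipped because the resulting peptide is
        # indistinguishable from N-terminal Met excision
        candidates = [
            (s, pos)
            for s in spans
            for pos in range(s.start, s.end)
            if not (pos == 1 and protein.sequence[0] == "M")
        ]
        n_full = len(spans)
        n_half = min(
            round_half_up(n_full * frac / (1.0 - frac)), len(candidates)
        )
        chosen_idx = ion_rng.choice(len(candidates), size=n_half, replace=False)
        chosen = [candidates[int(i)] for i in sorted(chosen_idx)]

        # designate perturbed sites among this protein's PK cuts
        pert_records: dict[int, dict] = {}
        if pid in perturbed:
            k = int(truth_rng.integers(k_lo, k_hi + 1))
            k = min(k, len(chosen))
            pick = truth_rng.choice(len(chosen), size=k, replace=False)
            for j in sorted(int(x) for x in pick):
                span, pos = chosen[j]
                exclusive = bool(truth_rng.random() < cfg.exclusive_site_prob)
                pert_records[pos] = {
                    "position": int(pos),
                    "fold": None if exclusive else float(cfg.site_effect_fold),
                    "exclusive": exclusive,
                }
            truth.perturbed_sites[pid] = [
                pert_records[pos] for pos in sorted(pert_records)
            ]

        # track PK consumption of parent tryptic peptides in the test condition
        parent_loss: dict = {}

        half_rows = []
        for span, pos in chosen:
            parent = full_int[span]
            h = parent * ion_rng.uniform(0.1, 0.5)
            # N-half keeps the tryptic N-terminus (PK C-terminus at pos);
            # C-half keeps the tryptic C-terminus (PK N-terminus at pos).
            if ion_rng.random() < 0.5:
                hs, he = span.start, pos
            else:
                hs, he = pos + 1, span.end
            rec = pert_records.get(pos)
            test_h, ref_h = h, h
            if rec is not None:
                if rec["exclusive"]:
                    ref_h = 0.0
                else:
                    test_h = h * rec["fold"]
                    parent_loss[span] = parent_loss.get(span, 0.0) + (test_h - h)
            half_rows.append((hs, he, test_h, ref_h, pos))

        def emit(rows, prov, start, end, test_v, ref_v, is_half, cut_pos):
            peptide = protein.sequence[start - 1 : end]
            for charge, scale in _charge_states(ion_rng):
                rows.append(
                    {
                        "protein_id": pid,
                        "peptide": peptide,
                        "charge": charge,
                        "mod_key": "m0",
                        "start": start,
                        "end": end,
                        "_test": test_v * scale * mult,
                        "_ref": ref_v * scale,
                    }
                )
                if prov is not None:
                    prov.append(
                        {
                            "protein_id": pid,
                            "start": start,
                            "end": end,
                            "charge": charge,
                            "is_half_tryptic": is_half,
                            "pk_position": cut_pos if is_half else -1,
                        }
                    )

        # LiP table: full-tryptic ions (PK-depleted for perturbed parents) ...
        for span in spans:
            f = full_int[span]
            f_test = max(f - parent_loss.get(span, 0.0), 0.05 * f)
            emit(lip_rows, lip_prov, span.start, span.end, f_test, f, False, -1)
        # ... plus half-tryptic ions
        for hs, he, test_h, ref_h, pos in half_rows:
            emit(lip_rows, lip_prov, hs, he, test_h, ref_h, True, pos)

        # control table: full-tryptic ions, no PK, plus a low level of
        # spurious half-tryptic ions (in-source fragmentation-like)
        for span in spans:
            f = full_int[span]
            emit(ctl_rows, None, span.start, span.end, f, f, False, -1)
        n_ctl_half = min(
            round_half_up(n_full * ctl_frac / (1.0 - ctl_frac)), len(chosen)
        )
        for span, pos in chosen[:n_ctl_half]:
            h = full_int[span] * 0.05
            emit(ctl_rows, None, span.start, pos, h, h, True, pos)

    lip = pd.DataFrame(lip_rows)
    ctl = pd.DataFrame(ctl_rows)
    provenance = pd.DataFrame(lip_prov)

    noise_rng = _rng(cfg, "noise")
    detect_rng = _rng(cfg, "detection")
    sigma = math.sqrt(math.log1p(cfg.cv**2))

    def expand(table: pd.DataFrame) -> pd.DataFrame:
        cols = {}
        for s in design.samples:
            base_col = "_test" if s.condition == cfg.test_condition else "_ref"
            base = table[base_col].to_numpy(dtype=float)
            noise = (
                np.exp(noise_rng.normal(0.0, sigma, size=len(table)))
                if sigma > 0
                else np.ones(len(table))
            )
            values = base * noise
            detected = (
                detect_rng.random(len(table)) < cfg.detection_prob
                if cfg.detection_prob < 1
                else np.ones(len(table), dtype=bool)
            )
            values = np.where(detected & (values > 0), values, np.nan)
            cols[s.sample_id] = values
        out = table[ION_KEY_COLUMNS].copy()
        for k, v in cols.items():
            out[k] = v
        return out

    lip_samples = [s.sample_id for s in design.samples if s.treatment == TREATMENT_LIP]
    ctl_samples = [s.sample_id for s in design.samples if s.treatment == TREATMENT_CONTROL]
    lip_table = expand(lip)[ION_KEY_COLUMNS + lip_samples]
    ctl_table = expand(ctl)[ION_KEY_COLUMNS + ctl_samples]
    # drop ions never observed anywhere (e.g. exclusive sites' empty side is
    # kept as NaN; a fully unobserved row carries no information)
    lip_keep = lip_table[lip_samples].notna().any(axis=1)
    lip_table = lip_table[lip_keep].reset_index(drop=True)
    provenance = provenance[lip_keep.to_numpy()].reset_index(drop=True)
    ctl_table = ctl_table[ctl_table[ctl_samples].notna().any(axis=1)].reset_index(
        drop=True
    )
    truth.validate()
    return lip_table, ctl_table, design, truth, provenance


def _charge_states(rng: np.random.Generator):
    """Most ions appear at one charge state; ~20% add a second one, which
    exercises ion-to-cut-site merging downstream."""
    if rng.random() < 0.2:
        return ((2, 0.7), (3, 0.3))
    return ((2, 1.0),)


def simulate_annotations(
    proteome: list[ProteinSeq],
    truth: SimTruth,
    cfg: SimConfig,
    planted_cofactor: str | None = None,
    planted_prob_perturbed: float = 0.6,
    base_cofactor_prob: float = 0.15,
) -> pd.DataFrame:
    """Random per-protein annotations (pI, domains, folds, cofactors, MW).

    When ``planted_cofactor`` is given, perturbed proteins carry that
    cofactor with probability ``planted_prob_perturbed`` against
    ``base_cofactor_prob`` in the background, planting a detectable
    feature association for enrichment tests.
    """
    rng = _rng(cfg, "annotation")
    perturbed = set(truth.perturbed_proteins)
    rows = []
    for protein in proteome:
        pid = protein.id
        n_domains = 1 + int(rng.poisson(0.8))
        xgroups = sorted(
            set(rng.choice(_XGROUP_VOCAB, size=n_domains, replace=True).tolist())
        )
        cofactors: list[str] = []
        if planted_cofactor is not None:
            p = planted_prob_perturbed if pid in perturbed else base_cofactor_prob
            if rng.random() < p:
                cofactors.append(planted_cofactor)
        for c in _COFACTOR_VOCAB:
            if c == planted_cofactor:
                continue
            if rng.random() < 0.06:
                cofactors.append(c)
        rows.append(
            {
                "protein_id": pid,
                "gene": pid.lower(),
                "pI": round(float(rng.uniform(4.0, 11.0)), 2),
                "n_domains": n_domains,
                "ecod_xgroups": ";".join(xgroups),
                "cofactors": ";".join(sorted(set(cofactors))),
                "mw_kda": round(len(protein) * 0.110, 1),
                "oligomeric_state": str(
                    rng.choice(["monomer", "dimer", "tetramer"])
                ),
            }
        )
    return pd.DataFrame(rows)


def simulate_dataset(
    cfg: SimConfig, planted_cofactor: str | None = None
) -> SimDataset:
    """Convenience wrapper: proteome + experiment + annotations."""
    proteome = simulate_proteome(cfg)
    lip, ctl, design, truth, provenance = simulate_experiment(proteome, cfg)
    annotations = simulate_annotations(
        proteome, truth, cfg, planted_cofactor=planted_cofactor
    )
    return SimDataset(cfg, proteome, lip, ctl, design, truth, annotations, provenance)


def write_fixture(dataset: SimDataset, directory) -> dict[str, Path]:
    """Write a complete fixture (FASTA, ion TSVs, design, annotations,
    truth JSON, provenance TSV) that round-trips through the package
    readers losslessly."""
    from . import io as lio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": directory / "proteome.fasta",
        "lip_ions": directory / "lip_ions.tsv",
        "control_ions": directory / "control_ions.tsv",
        "design": directory / "design.tsv",
        "annotations": directory / "annotations.tsv",
        "truth": directory / "truth.json",
        "provenance": directory / "lip_provenance.tsv",
        "config": directory / "sim_config.json",
    }
    lio.write_fasta(dataset.proteome, paths["fasta"])
    lio.write_ion_table(dataset.lip_ions, paths["lip_ions"])
    lio.write_ion_table(dataset.control_ions, paths["control_ions"])
    lio.write_design(dataset.design, paths["design"])
    lio.write_annotations(dataset.annotations, paths["annotations"])
    paths["truth"].write_text(dataset.truth.to_json())
    dataset.lip_provenance.to_csv(paths["provenance"], sep="\t", index=False)
    cfg = asdict(dataset.config)
    paths["config"].write_text(json.dumps(cfg, indent=1, default=list))
    return paths
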