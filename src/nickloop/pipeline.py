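"""End-to-end scenario orchestration.

Ties the stages together for the two biological endpoints studied on
CAG-repeat looped plasmids:

* **expansion** — MutSbeta-MutLgamma incisions on the strand opposite the
  loop (5' of it), followed by displacement synthesis that copies the loop:
  the opposite strand gains the loop's reverse complement, quantified by
  trace decomposition as a +L insertion.
* **contraction** — FAN1 (with RFC-PCNA) incision one nucleotide 3' of the
  loop on the looped strand, loop excision and resynthesis: the looped
  strand loses the loop, quantified as a -L deletion.

The standard substrate is a synthetic 3.2 kb circular plasmid carrying a
12-nt (CAG)4 extrahelical loop on the top strand, emulating the scale and
architecture of the study's looped heteroduplex plasmids.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np

from nickloop import gloesim, nickmap, substrates, tracedecomp
from nickloop.errors import ConfigError
from nickloop.substrates import TOP, HeteroduplexSubstrate, revcomp

logger = logging.getLogger("nickloop")

# planted indel fractions emulating the study's reported trace signals:
# 15.5% (CTG)4 insertion in the flap-processing-supplemented expansion
# reaction; "vast majority" (>70%) loop loss in the contraction reaction.
EXPANSION_FRACTION = 0.155
CONTRACTION_FRACTION = 0.75

STANDARD_LOOP = "CAG" * 4
STANDARD_LENGTH = 3200
STANDARD_INSERTION_POINT = 1000


def make_standard_substrate(seed: int = 7, length_nt: int = STANDARD_LENGTH,
                            loop_sequence: str = STANDARD_LOOP,
                            insertion_point: int = STANDARD_INSERTION_POINT,
                            carrier_strand: str = TOP,
                            gc_fraction: float = 0.5) -> HeteroduplexSubstrate:
    """Synthetic stand-in for the looped 3.2 kb plasmid substrate."""
    plasmid = substrates.generate_plasmid(length_nt, gc_fraction, seed,
                                          name=f"synthetic_pSam_seed{seed}")
    loop = substrates.LoopSpec(carrier_strand, insertion_point, loop_sequence)
    return substrates.make_heteroduplex(plasmid, loop)


# ---------------------------------------------------------------------------
# Sanger read-out regions
# ---------------------------------------------------------------------------

def _circular_slice(seq: str, start: int, length: int) -> str:
    tiled = seq * (length // len(seq) + 2)
    return tiled[start % len(seq):start % len(seq) + length]


def expansion_readout(substrate: HeteroduplexSubstrate, upstream: int = 40,
                      downstream: int = 200) -> Tuple[str, str, int]:
    """Control and expansion-product read-outs of the strand opposite the loop.

    Returns ``(control_region, product_region, target_site)``: linear
    sequences as a sequencing primer placed ``upstream`` nt 5' of the loop
    site on the opposite strand would read them, with the indel site at
    region coordinate ``target_site``.
    """
    n, i = substrate.N, substrate.loop.insertion_point
    site_native = n - i  # opposite-strand native coordinate of the loop gap
    start = site_native - upstream
    control = _circular_slice(substrate.opposite_strand_seq, start, upstream + downstream)
    expanded = substrates.expansion_product(substrate)
    product_strand = expanded.bottom if substrate.looped_strand == TOP else expanded.top
    product = _circular_slice(product_strand, start, upstream + downstream + substrate.L)
    return control, product, upstream


def contraction_readout(substrate: HeteroduplexSubstrate, upstream: int = 40,
                        downstream: int = 200) -> Tuple[str, str, int]:
    """Control and contraction-product read-outs of the looped strand.

    The control is read from the looped strand (loop included); the product
    from the loop-free carrier strand.  Both start at the same physical
    position ``upstream`` nt 5' of the loop.
    """
    i = substrate.loop.insertion_point
    start = i - upstream
    control = _circular_slice(substrate.looped_strand_seq, start,
                              upstream + downstream + substrate.L)
    contracted = substrates.contraction_product(substrate)
    product_strand = contracted.top if substrate.looped_strand == TOP else contracted.bottom
    product = _circular_slice(product_strand, start, upstream + downstream)
    return control, product, upstream


def expansion_insert_unit(substrate: HeteroduplexSubstrate) -> str:
    """Repeat unit expected in the opposite strand upon expansion (e.g. CTG)."""
    rc = revcomp(substrate.loop.loop_sequence)
    unit = rc[:3] if len(rc) >= 3 and rc == rc[:3] * (len(rc) // 3) else rc
    return unit


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All parameters of a demo run; round-trips through JSON/YAML."""

    scenario: str = "expansion"
    substrate_file: Optional[str] = None  # JSON substrate; None -> standard synthetic
    substrate_seed: int = 7
    n_reads: int = 20000
    read_length: int = 75
    error_rate: float = 0.001
    seed: int = 1
    trace_noise_sd: float = 0.01
    trace_decay_rate: float = tracedecomp.DEFAULT_DECAY_RATE
    planted_fraction: Optional[float] = None  # None -> scenario default
    n_trace_replicates: int = 5
    seed_k: int = 20
    max_mismatches: int = 2
    copies: str = "middle"
    shift_min: int = -15
    shift_max: int = 15
    alpha: float = tracedecomp.DEFAULT_ALPHA
    out_prefix: str = "nickloop_run"

    def to_dict(self) -> Dict:
        return dataclasses.asdict(self)

    @staticmethod
    def from_dict(d: Dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(RunConfig)}
        extra = set(d) - known
        if extra:
            raise ConfigError(f"unknown config keys: {sorted(extra)}")
        return RunConfig(**d)

    @staticmethod
    def from_file(path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml
            d = yaml.safe_load(text)
        else:
            d = json.loads(text)
        if not isinstance(d, dict):
            raise ConfigError("config file must hold a mapping")
        return RunConfig.from_dict(d)

    def resolve_substrate(self) -> HeteroduplexSubstrate:
        if self.substrate_file:
            return HeteroduplexSubstrate.from_json(self.substrate_file)
        return make_standard_substrate(seed=self.substrate_seed)

    def resolved_planted_fraction(self) -> float:
        if self.planted_fraction is not None:
            return self.planted_fraction
        return EXPANSION_FRACTION if self.scenario == "expansion" else CONTRACTION_FRACTION


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def _setup_logging(outdir: Path, verbose: bool = False) -> None:
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for handler in (logging.StreamHandler(sys.stderr),
                    logging.FileHandler(outdir / "run.log", mode="w")):
        handler.setFormatter(fmt)
        logger.addHandler(handler)


# ---------------------------------------------------------------------------
# decomposition batteries
# ---------------------------------------------------------------------------

def decompose_mixture(substrate: HeteroduplexSubstrate, scenario: str,
                      planted_fraction: float, noise_sd: float,
                      seed: int, shift_range=(-15, 15),
                      alpha: float = tracedecomp.DEFAULT_ALPHA,
                      decay_rate: float = tracedecomp.DEFAULT_DECAY_RATE):
    """Simulate and decompose one mutant trace for a scenario.

    Returns ``(result, summary, templates, mutant_trace)``; the planted
    component is the +L insertion (expansion) or -L deletion (contraction)
    at ``planted_fraction``.
    """
    if scenario == "expansion":
        control, product, site = expansion_readout(substrate)
        insert_unit = expansion_insert_unit(substrate)
    elif scenario == "contraction":
        control, product, site = contraction_readout(substrate)
        insert_unit = substrate.loop.loop_sequence[:3]
    else:
        raise ConfigError(f"unknown scenario {scenario!r}")
    mixture = [(control, 1.0 - planted_fraction), (product, planted_fraction)]
    mutant = tracedecomp.simulate_trace(mixture, decay_rate=decay_rate,
                                        noise_sd=noise_sd, seed=seed)
    templates = tracedecomp.build_templates(control, site, shift_range,
                                            expected_insert_bases=insert_unit,
                                            decay_rate=decay_rate)
    result = tracedecomp.decompose(mutant, templates, alpha=alpha)
    summary = tracedecomp.summarize_indels(result, substrate)
    return result, summary, templates, mutant


def replicate_recovery(substrate: HeteroduplexSubstrate, scenario: str,
                       planted_fraction: float, noise_sd: float,
                       seeds, **kwargs) -> Dict:
    """Planted-fraction recovery across seeded replicate traces."""
    planted_shift = substrate.L if scenario == "expansion" else -substrate.L
    recovered, dominant_ok = [], 0
    for s in seeds:
        result, summary, _, _ = decompose_mixture(
            substrate, scenario, planted_fraction, noise_sd, int(s), **kwargs)
        recovered.append(result.fraction(planted_shift))
        if summary["dominant_shift"] == planted_shift:
            dominant_ok += 1
    recovered = np.array(recovered)
    return {
        "scenario": scenario,
        "planted_fraction": planted_fraction,
        "planted_shift": int(planted_shift),
        "n_replicates": len(recovered),
        "mean_recovered": float(recovered.mean()),
        "sd_recovered": float(recovered.std(ddof=1)) if len(recovered) > 1 else 0.0,
        "dominant_component_correct": dominant_ok,
    }


# ---------------------------------------------------------------------------
# demo runs
# ---------------------------------------------------------------------------

def _run_demo(config: RunConfig, nick_scenario: str, verbose: bool = False) -> Dict:
    outdir = Path(config.out_prefix)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir, verbose)
    stage = "setup"
    try:
        logger.info("config: %s", json.dumps(config.to_dict(), sort_keys=True))
        substrate = config.resolve_substrate()
        substrate.to_json(outdir / "substrate.json")
        substrates.write_plasmid(substrate.plasmid, outdir / "plasmid.fasta")
        logger.info("substrate: N=%d L=%d looped=%s insertion=%d",
                    substrate.N, substrate.L, substrate.looped_strand,
                    substrate.loop.insertion_point)

        stage = "nick simulation"
        profile = gloesim.preset_profile(nick_scenario, substrate)
        readset = gloesim.simulate_reads(profile, config.n_reads,
                                         read_length=config.read_length,
                                         error_rate=config.error_rate,
                                         seed=config.seed)
        fastq = outdir / "reads.fastq"
        readset.write_fastq(fastq)
        readset.write_truth(outdir / "truth.tsv")
        logger.info("simulated %d reads (%s scenario) -> %s [sha %s]",
                    config.n_reads, nick_scenario, fastq, _sha256(fastq))

        stage = "nick mapping"
        cut_profile = nickmap.run_nickmap(
            substrate, readset.reads, seed_k=config.seed_k,
            max_mismatches=config.max_mismatches, copies=config.copies)
        artifact_paths = nickmap.export_profile(cut_profile, outdir / "cuts")
        logger.info("cut totals: %s", cut_profile.totals)
        for kind, p in artifact_paths.items():
            logger.info("wrote %s [%s]", p, _sha256(p))

        stage = "trace decomposition"
        planted = config.resolved_planted_fraction()
        trace_seeds = [config.seed + 1000 + r for r in range(config.n_trace_replicates)]
        recovery = replicate_recovery(
            substrate, config.scenario, planted, config.trace_noise_sd, trace_seeds,
            shift_range=(config.shift_min, config.shift_max), alpha=config.alpha,
            decay_rate=config.trace_decay_rate)
        result, decomp_summary, templates, mutant = decompose_mixture(
            substrate, config.scenario, planted, config.trace_noise_sd,
            trace_seeds[0], shift_range=(config.shift_min, config.shift_max),
            alpha=config.alpha, decay_rate=config.trace_decay_rate)
        tracedecomp.write_chromatogram_tsv(mutant, outdir / "mutant_trace.tsv")
        result.to_frame().to_csv(outdir / "decomposition.tsv", sep="\t", index=False)
        result.to_json(outdir / "decomposition.json")
        tracedecomp.plot_decomposition(mutant, templates, result,
                                       outdir / "decomposition.svg")
        logger.info("decomposition: %s", decomp_summary["call"])

        stage = "report"
        looped = substrate.looped_strand
        opposite = substrate.opposite_strand
        report = {
            "config": config.to_dict(),
            "nick_scenario": nick_scenario,
            "cut_totals": cut_profile.totals,
            "cut_fraction_looped_strand": _strand_fraction(cut_profile, looped),
            "cut_fraction_opposite_strand": _strand_fraction(cut_profile, opposite),
            "modal_cut_looped_strand_plasmid": cut_profile.modal_cut(looped),
            "loop3_boundary_plus1_plasmid": _loop3p1_plasmid(substrate),
            "planted_fraction": planted,
            "recovery": recovery,
            "decomposition": decomp_summary,
        }
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=1)
            fh.write("\n")
        logger.info("report written to %s", outdir / "report.json")
        return report
    except Exception:
        logger.exception("stage failed: %s", stage)
        raise RuntimeError(f"demo failed during stage: {stage}")


def _strand_fraction(profile: nickmap.CutProfile, strand: str) -> float:
    total = (profile.counts_top.sum() + profile.counts_bottom.sum()
             + profile.loop_local_counts.sum())
    if total == 0:
        return 0.0
    return float(profile.strand_counts(strand).sum() / total)


def _loop3p1_plasmid(substrate: HeteroduplexSubstrate) -> int:
    """Plasmid coordinate of the looped-strand position 1 nt 3' of the loop."""
    q = (substrate.loop3_boundary + 1) % (substrate.N + substrate.L)
    d = substrate.looped_to_duplex(q)
    return d if substrate.looped_strand == TOP else substrate.N - 1 - d


def run_expansion_demo(config: Optional[RunConfig] = None, verbose: bool = False) -> Dict:
    """Expansion scenario end to end: opposite-strand 5'-of-loop incisions,
    nick mapping, and decomposition of (CTG)4-insertion trace mixtures."""
    config = config or RunConfig(scenario="expansion", out_prefix="expansion_demo")
    if config.scenario != "expansion":
        config = dataclasses.replace(config, scenario="expansion")
    return _run_demo(config, "mutl_opposite_5prime", verbose)


def run_contraction_demo(config: Optional[RunConfig] = None, verbose: bool = False) -> Dict:
    """Contraction scenario end to end: looped-strand incision 1 nt 3' of the
    loop, nick mapping, and decomposition of loop-loss trace mixtures."""
    config = config or RunConfig(scenario="contraction", out_prefix="contraction_demo")
    if config.scenario != "contraction":
        config = dataclasses.replace(config, scenario="contraction")
    return _run_demo(config, "fan1_loop3prime", verbose)
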