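"""Simulate the two emulated breeding populations and write their genotype,
pedigree, phenotype and gene-annotation files.

Run from the repository root:  python analysis/01_simulate.py
"""

import importlib.util
from pathlib import Path

HERE = Path(__file__).resolve().parent
spec = importlib.util.spec_from_file_location("cfg", HERE / "00_config.py")
cfg = importlib.util.module_from_spec(spec)
spec.loader.exec_module(cfg)

import treegs
import treegs.simpop as sp
from treegs import io


def main():
    cfg.DATA.mkdir(parents=True, exist_ok=True)
    for name, sim_cfg in (("popA", cfg.POP_A), ("popB", cfg.POP_B)):
        sim = treegs.simulate_population(sim_cfg)
        out = cfg.DATA / name
        out.mkdir(exist_ok=True)
        io.write_plink(sim.genotypes, out / "genotypes")
        io.write_phenotypes(sim.phenotypes, out / "phenotypes.csv")
        sim.pedigree.to_csv(out / "pedigree.csv", index=False)
        io.write_truth_json(
            {k: v for k, v in sim.truth.items() if k != "qtl_idx"},
            out / "truth.json")
        genes = sp.annotate_genes(sim.genotypes.chrom, sim.genotypes.pos_bp,
                                  sim_cfg.chrom_len_bp, genic_fraction=0.526,
                                  seed=sim_cfg.seed)
        io.write_bed_intervals(genes, out / "genes.bed")
        print(f"{name}: {sim.genotypes.n_samples} trees x "
              f"{sim.genotypes.n_markers} markers, realized h2 = "
              f"{sim.truth['realized_h2']:.3f}")


if __name__ == "__main__":
    main()
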