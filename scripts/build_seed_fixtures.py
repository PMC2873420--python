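"""Regenerate the packaged synthetic seed fixtures (committed under src/rfxsurvey/data/).

Deterministic: re-running reproduces the committed files byte for byte.
The DBD seed family emulates the real query set's shape — four 76-aa domains
from one ancestor at moderate within-family divergence, nine shared anchor
positions held invariant; the 24 IFT query stand-ins are background peptides
of 200-400 residues; profile instance sets are eight aligned copies of a
consensus per domain at 15% divergence.
"""

from pathlib import Path

from rfxsurvey.domain_search import QueryDomain, derive_seed
from rfxsurvey.io_formats import ProteinRecord, write_fasta
from rfxsurvey.ift_scan import IFT_MODULES
from rfxsurvey.resources import DBD_ANCHORS, DBD_LENGTH
from rfxsurvey.synthetic import evolve_domain, random_proteins

DATA = Path(__file__).resolve().parents[1] / "src" / "rfxsurvey" / "data"
MASTER = 20100504  # fixed fixture seed

SEED_NAMES = ("seed_hRFX1_like", "seed_DAF19_like", "seed_dRFX_like",
              "seed_sRFX1_like")
PROFILE_SPECS = {"AD": 30, "B": 24, "C": 24, "D": 20, "DD": 40}


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)

    # --- DBD seed family -----------------------------------------------------
    ancestor = random_proteins(1, (DBD_LENGTH, DBD_LENGTH),
                               derive_seed(MASTER, "dbd_ancestor"))[0].sequence
    anc = QueryDomain("ancestor", ancestor, DBD_ANCHORS)
    records = []
    for k, name in enumerate(SEED_NAMES):
        seq = evolve_domain(anc, 0.18, True, derive_seed(MASTER, "dbd", k))
        records.append(ProteinRecord(name, "", seq, "synthetic DBD seed"))
    write_fasta(records, DATA / "rfx_dbd_seeds_synthetic.fasta")
    anchor_str = ",".join(str(a) for a in sorted(DBD_ANCHORS))
    with open(DATA / "dbd_anchors_synthetic.tsv", "w") as fh:
        fh.write("# seed name -> 0-based anchor positions\n")
        for name in SEED_NAMES:
            fh.write(f"{name}\t{anchor_str}\n")

    # --- IFT/BBS query stand-ins --------------------------------------------
    ift_records = []
    for mod, genes in IFT_MODULES:
        for g in genes:
            prot = random_proteins(1, (200, 400), derive_seed(MASTER, "ift", g))[0]
            ift_records.append(ProteinRecord(g, "", prot.sequence,
                                             f"synthetic stand-in ({mod})"))
    write_fasta(ift_records, DATA / "ift_queries_synthetic.fasta")

    # --- profile instance alignments ----------------------------------------
    prof_records = []
    for dom, length in PROFILE_SPECS.items():
        consensus = random_proteins(1, (length, length),
                                    derive_seed(MASTER, "prof", dom))[0].sequence
        cons = QueryDomain(f"{dom}_consensus", consensus, frozenset())
        for k in range(8):
            seq = evolve_domain(cons, 0.15, False,
                                derive_seed(MASTER, "prof", dom, k))
            prof_records.append(ProteinRecord(f"{dom}_{k + 1}", "", seq,
                                              "synthetic aligned instance"))
    write_fasta(prof_records, DATA / "profile_instances_synthetic.fasta")
    print(f"fixtures written to {DATA}")


if __name__ == "__main__":
    main()
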