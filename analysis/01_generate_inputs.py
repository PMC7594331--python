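"""Generate the analysis inputs.

The source GWAS summary statistics (a GDF-15 pQTL study and the stroke/AF/
HF/NICM/CAD-MI disease consortia) are not redistributable, so this step
writes their synthetic stand-ins: the nine-SNP GDF-15 candidate-instrument
fixture (real rsIDs, constructed numerics) with one synthetic outcome study
per cardiovascular endpoint, plus the pairwise LD matrix.
"""

from pathlib import Path

from gdf15mr import gdf15_fixture
from gdf15mr.sumstats_io import write_ld_matrix, write_sumstats

DATA = Path(__file__).resolve().parent.parent / "results" / "inputs"


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    exposure, ld, outcomes = gdf15_fixture()
    write_sumstats(exposure, DATA / "exposure_gdf15.tsv")
    write_ld_matrix(ld, DATA / "ld.tsv")
    for label, stats in outcomes.items():
        write_sumstats(stats, DATA / f"outcome_{label}.tsv")
    print(f"exposure study: {len(exposure)} candidate SNPs -> {DATA / 'exposure_gdf15.tsv'}")
    print(f"outcome studies: {', '.join(outcomes)} ({len(outcomes)} endpoints)")
    print(f"LD matrix over {len(ld.rsids)} SNPs -> {DATA / 'ld.tsv'}")


if __name__ == "__main__":
    main()
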