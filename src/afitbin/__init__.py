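"""afitbin: metagenomic contig binning from AFIT composition vectors and coverage.

The pipeline represents every contig by a 90-dimensional strand-invariant
composition vector (aggregate l-mer counts keyed by the reverse-complement
class of each substring's initial/terminal dinucleotide) plus a normal-model
coverage distance, estimates the number of bins with a grow-until-empty
clustering rule, clusters long contigs by a coverage-penalized matrix
factorization, and finally places short contigs by a combined
composition + coverage score.
"""

from .afit import (
    AfitMatrix,
    AfitVector,
    ClassPartition,
    build_twomer_classes,
    compute_afit,
    compute_afit_matrix,
    reverse_complement,
)
from .binning import (
    FactorizationResult,
    assign_short_contigs,
    combined_distance_matrix,
    estimate_num_bins,
    fit_factorization,
    harden_assignments,
    run_afitbin,
    split_by_length,
)
from .coverage import (
    CoverageProfile,
    build_coverage_matrix,
    coverage_distance,
    coverage_matrix_from_depth,
    normal_nonshared_area,
)
from .evaluation import (
    ConfusionMatrix,
    SeparationSummary,
    compute_tnf,
    confusion_matrix,
    distance_separation_summary,
    f_score,
    precision,
    recall,
)
from .io_formats import (
    BinningResult,
    ContigRecord,
    DepthTable,
    read_depth_table,
    read_fasta,
    read_truth_table,
    write_bins,
    write_depth_table,
    write_fasta,
)
from .simulate import (
    CommunitySpec,
    SyntheticCommunity,
    generate_community,
    generate_genome,
    write_community,
)

__version__ = "1.0.0"
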