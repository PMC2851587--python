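"""pepquant: label-free LC-MS peptidomics quantification and class modelling.

A reusable pipeline for peptide-level label-free LC-MS experiments with a
factorial design: two-step normalization (median-reference calibration and
run-order lowess drift correction), group-missingness filtering, multivariate
class modelling (PCA and PLS-DA with VIP and jackknife confidence intervals),
per-peptide three-way factorial differential expression with FDR control, and
a peptide mass / prohormone cleavage toolkit, exercised end-to-end on a
synthetic-data generator with known ground truth.
"""

__version__ = "0.1.0"

from .catalog import (ModificationSpec, PeptideRecord, enumerate_candidate_peptides,
                      find_cleavage_sites, load_catalog, monoisotopic_mh)
from .dataio import (IntensityMatrix, drop_runs, group_labels, read_design,
                     read_matrix, write_design, write_matrix)
from .differential import FactorialAnova, adjust_fdr, analyze_all, fit_factorial, pairwise_t
from .multivariate import (PLSDA, CrossValidatedPCA, compute_vip, fit_pca,
                           fit_plsda, group_median_transform,
                           hierarchical_cluster, jackknife_vip)
from .normalize import (GroupMissingFilter, RunCalibrator, RunOrderCorrector,
                        build_reference_run, calibrate_to_reference,
                        collapse_technical_replicates, correct_run_order,
                        filter_min_matching, flag_outlier_runs, log2_transform)
from .pipeline import PipelineConfig, run_pipeline
from .simulate import SimulationConfig, generate_design, simulate_intensities, study_config
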