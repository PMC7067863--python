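"""Pipeline-wide default thresholds.

Every stage of the peak caller and the differential analysis reads its
cut-offs from this table, so a single frozen dict documents the whole
decision funnel: 100-bp windows stepping by 50 bp, the >10-read IP coverage
filter, the four detector thresholds, the >=3-sample / >=3-technique
consensus rules, the 150-bp final peak width, the CPM inclusion filters and
the significance cut-offs of the moderated linear models.
"""

from __future__ import annotations

from types import MappingProxyType

DEFAULTS = MappingProxyType(
    {
        # window grid
        "window_size": 100,
        "window_step": 50,
        "read_length": 65,
        # per-sample IP coverage filter (strict >)
        "min_ip_reads": 10,
        # detectors
        "fisher_alpha": 0.001,  # BH-adjusted p < alpha
        "rpmf_threshold": 10.0,  # RPM(IP) - RPM(Input) > threshold
        "pom_min": 4.0,  # windows with IP POM < 4 removed
        "poi_min": 2.0,  # pass iff POI > 2
        "poisson_qmax": 0.05,  # local-Poisson enrichment q-value
        # consensus
        "min_samples": 3,  # window must pass in >= 3 IP samples
        "min_techniques": 3,  # site must be found by >= 3 of 4 techniques
        "peak_width": 150,
        # motif weights (RGACW variants)
        "motif_weights": MappingProxyType(
            {"GAACA": 2, "GGACA": 3, "GAACT": 5, "GGACT": 8}
        ),
        # differential analysis
        "min_cpm": 5.0,
        "min_cpm_samples": 3,
        "min_cpm_per_procedure": 2,  # >=5 CPM in >=2 IP and Input samples
        "lfc_threshold": 1.0,  # |log2FC| > 1
        "adj_p_threshold": 0.05,  # BH-adjusted p < 0.05
    }
)
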