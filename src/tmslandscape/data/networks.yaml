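# Functional-network definitions: ordered constituent regions per network.
#
# Each entry maps a network name to the ordered list of its regions of
# interest (ROIs).  The order fixes the bit order of binary activity
# patterns, so edit with care: pattern codes are only comparable between
# runs that used the same region order.
#
# The default-mode network ships without a constituent list in this
# default atlas; add an entry here to include it in an analysis.
sensorimotor:
  - Left Precentral Gyrus
  - Left Postcentral Gyrus
  - Paracentral Lobule
  - Right Precentral Gyrus
  - Right Postcentral Gyrus
visual:
  - Pericalcarine Gyrus
  - Lingual Gyrus
  - Lateral Occipital Gyrus
  - Fusiform Gyrus
  - Cuneus Gyrus
auditory:
  - Left Supramarginal Gyrus
  - Left Superior Temporal Gyrus
  - Right Supramarginal Gyrus
  - Right Superior Temporal Gyrus
  - Transverse Temporal Gyrus
frontoparietal:
  - Left Superior Frontal Gyrus
  - Right Superior Frontal Gyrus
  - Rostral Middle Frontal Gyrus
  - Caudal Middle Frontal Gyrus
  - Pars Triangularis Gyrus
  - Medial Orbitofrontal Gyrus
  - Inferior Parietal Gyrus
salience:
  - Caudal Anterior Cingulate Gyrus
  - Caudal Middle Frontal Gyrus
  - Insula Gyrus
  - Pars Triangularis Gyrus
  - Rostral Anterior Cingulate Gyrus
  - Rostral Middle Frontal Gyrus
  - Superior Parietal Gyrus
attention:
  - Right Superior Temporal Gyrus
  - Left Superior Temporal Gyrus
  - Superior Parietal Gyrus
  - Pars Triangularis Gyrus
  - Inferior Parietal Gyrus
  - Rostral Middle Frontal Gyrus
  - Caudal Middle Frontal Gyrus
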