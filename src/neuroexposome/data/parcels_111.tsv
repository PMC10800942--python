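Left Frontal Pole
Left Insular Cortex
Left Superior Frontal Gyrus
Left Middle Frontal Gyrus
Left Inferior Frontal Gyrus, pars triangularis
Left Inferior Frontal Gyrus, pars opercularis
Left Precentral Gyrus
Left Temporal Pole
Left Superior Temporal Gyrus, anterior division
Left Superior Temporal Gyrus, posterior division
Left Middle Temporal Gyrus, anterior division
Left Middle Temporal Gyrus, posterior division
Left Middle Temporal Gyrus, temporooccipital part
Left Inferior Temporal Gyrus, anterior division
Left Inferior Temporal Gyrus, posterior division
Left Inferior Temporal Gyrus, temporooccipital part
Left Postcentral Gyrus
Left Superior Parietal Lobule
Left Supramarginal Gyrus, anterior division
Left Supramarginal Gyrus, posterior division
Left Angular Gyrus
Left Lateral Occipital Cortex, superior division
Left Lateral Occipital Cortex, inferior division
Left Intracalcarine Cortex
Left Frontal Medial Cortex
Left Juxtapositional Lobule Cortex
Left Subcallosal Cortex
Left Paracingulate Gyrus
Left Cingulate Gyrus, anterior division
Left Cingulate Gyrus, posterior division
Left Precuneous Cortex
Left Cuneal Cortex
Left Frontal Orbital Cortex
Left Parahippocampal Gyrus, anterior division
Left Parahippocampal Gyrus, posterior division
Left Lingual Gyrus
Left Temporal Fusiform Cortex, anterior division
Left Temporal Fusiform Cortex, posterior division
Left Temporal Occipital Fusiform Cortex
Left Occipital Fusiform Gyrus
Left Frontal Operculum Cortex
Left Central Opercular Cortex
Left Parietal Operculum Cortex
Left Planum Polare
Left Heschl's Gyrus
Left Planum Temporale
Left Supracalcarine Cortex
Left Occipital Pole
Right Frontal Pole
Right Insular Cortex
Right Superior Frontal Gyrus
Right Middle Frontal Gyrus
Right Inferior Frontal Gyrus, pars triangularis
Right Inferior Frontal Gyrus, pars opercularis
Right Precentral Gyrus
Right Temporal Pole
Right Superior Temporal Gyrus, anterior division
Right Superior Temporal Gyrus, posterior division
Right Middle Temporal Gyrus, anterior division
Right Middle Temporal Gyrus, posterior division
Right Middle Temporal Gyrus, temporooccipital part
Right Inferior Temporal Gyrus, anterior division
Right Inferior Temporal Gyrus, posterior division
Right Inferior Temporal Gyrus, temporooccipital part
Right Postcentral Gyrus
Right Superior Parietal Lobule
Right Supramarginal Gyrus, anterior division
Right Supramarginal Gyrus, posterior division
Right Angular Gyrus
Right Lateral Occipital Cortex, superior division
Right Lateral Occipital Cortex, inferior division
Right Intracalcarine Cortex
Right Frontal Medial Cortex
Right Juxtapositional Lobule Cortex
Right Subcallosal Cortex
Right Paracingulate Gyrus
Right Cingulate Gyrus, anterior division
Right Cingulate Gyrus, posterior division
Right Precuneous Cortex
Right Cuneal Cortex
Right Frontal Orbital Cortex
Right Parahippocampal Gyrus, anterior division
Right Parahippocampal Gyrus, posterior division
Right Lingual Gyrus
Right Temporal Fusiform Cortex, anterior division
Right Temporal Fusiform Cortex, posterior division
Right Temporal Occipital Fusiform Cortex
Right Occipital Fusiform Gyrus
Right Frontal Operculum Cortex
Right Central Opercular Cortex
Right Parietal Operculum Cortex
Right Planum Polare
Right Heschl's Gyrus
Right Planum Temporale
Right Supracalcarine Cortex
Right Occipital Pole
Left Thalamus
Left Caudate
Left Putamen
Left Pallidum
Left Hippocampus
Left Amygdala
Left Accumbens
Right Thalamus
Right Caudate
Right Putamen
Right Pallidum
Right Hippocampus
Right Amygdala
Right Accumbens
Brainstem
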