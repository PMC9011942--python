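# Illustrative default lexicon for the three organ systems.  Built from the
# descriptor taxonomy and documented term examples; NOT an exhaustive
# institutional dictionary.  Wildcards (*) absorb trailing-character
# misspellings and inflections.

# --- organ descriptors -----------------------------------------------------
- {pattern: lung, class: organ, organ: lungs_pleura}
- {pattern: lungs, class: organ, organ: lungs_pleura}
- {pattern: pulmonary, class: organ, organ: lungs_pleura}
- {pattern: pleura, class: organ, organ: lungs_pleura}
- {pattern: pleural, class: organ, organ: lungs_pleura}
- {pattern: airspace, class: organ, organ: lungs_pleura}
- {pattern: liver, class: organ, organ: liver_gallbladder}
- {pattern: hepatic, class: organ, organ: liver_gallbladder}
- {pattern: intrahepatic, class: organ, organ: liver_gallbladder}
- {pattern: gallbladder, class: organ, organ: liver_gallbladder}
- {pattern: biliary, class: organ, organ: liver_gallbladder}
- {pattern: bile, class: organ, organ: liver_gallbladder}
- {pattern: kidney, class: organ, organ: kidneys_ureters}
- {pattern: kidneys, class: organ, organ: kidneys_ureters}
- {pattern: renal, class: organ, organ: kidneys_ureters}
- {pattern: ureter, class: organ, organ: kidneys_ureters}
- {pattern: ureters, class: organ, organ: kidneys_ureters}

# --- single-organ disease descriptors --------------------------------------
- {pattern: atelectasis, class: single_organ, organ: lungs_pleura, label: atelectasis}
- {pattern: 'atelect*', class: single_organ, organ: lungs_pleura, label: atelectasis}
- {pattern: emphysema, class: single_organ, organ: lungs_pleura, label: emphysema}
- {pattern: 'emphys*', class: single_organ, organ: lungs_pleura, label: emphysema}
- {pattern: effusion, class: single_organ, organ: lungs_pleura, label: effusion}
- {pattern: effusions, class: single_organ, organ: lungs_pleura, label: effusion}
- {pattern: 'effus*', class: single_organ, organ: lungs_pleura, label: effusion}
- {pattern: pleural effusion, class: single_organ, organ: lungs_pleura, label: effusion}
- {pattern: steatosis, class: single_organ, organ: liver_gallbladder, label: fatty}
- {pattern: 'steato*', class: single_organ, organ: liver_gallbladder, label: fatty}
- {pattern: cholelithiasis, class: single_organ, organ: liver_gallbladder, label: stone}
- {pattern: 'choleli*', class: single_organ, organ: liver_gallbladder, label: stone}
- {pattern: nephrolithiasis, class: single_organ, organ: kidneys_ureters, label: stone}
- {pattern: 'nephroli*', class: single_organ, organ: kidneys_ureters, label: stone}

# --- multi-organ disease descriptors (need an organ co-mention) ------------
- {pattern: nodule, class: multi_organ, label: nodule}
- {pattern: nodules, class: multi_organ, label: nodule}
- {pattern: 'nodul*', class: multi_organ, label: nodule}
- {pattern: mass, class: multi_organ, label: nodule}
- {pattern: masses, class: multi_organ, label: nodule}
- {pattern: stone, class: multi_organ, label: stone}
- {pattern: stones, class: multi_organ, label: stone}
- {pattern: 'ston*', class: multi_organ, label: stone}
- {pattern: lesion, class: multi_organ, label: lesion}
- {pattern: lesions, class: multi_organ, label: lesion}
- {pattern: 'lesio*', class: multi_organ, label: lesion}
- {pattern: cyst, class: multi_organ, label: cyst}
- {pattern: cysts, class: multi_organ, label: cyst}
- {pattern: 'cyst*', class: multi_organ, label: cyst}
- {pattern: atrophy, class: multi_organ, label: atrophy}
- {pattern: atrophic, class: multi_organ, label: atrophy}
- {pattern: 'atroph*', class: multi_organ, label: atrophy}
- {pattern: dilation, class: multi_organ, label: dilation}
- {pattern: dilatation, class: multi_organ, label: dilation}
- {pattern: dilated, class: multi_organ, label: dilation}
- {pattern: 'dilat*', class: multi_organ, label: dilation}
- {pattern: fatty, class: multi_organ, label: fatty}
- {pattern: 'fatt*', class: multi_organ, label: fatty}

# --- negation terms --------------------------------------------------------
- {pattern: 'no', class: negation}  # quoted: bare "no" is YAML for false
- {pattern: without, class: negation}
- {pattern: negative for, class: negation}
- {pattern: free of, class: negation}
- {pattern: absent, class: negation}

# --- qualifier terms -------------------------------------------------------
- {pattern: however, class: qualifier}
- {pattern: although, class: qualifier}
- {pattern: whereas, class: qualifier}

# --- normal terms ----------------------------------------------------------
- {pattern: unremarkable, class: normal, organ: lungs_pleura}
- {pattern: clear, class: normal, organ: lungs_pleura}
- {pattern: normal, class: normal, organ: lungs_pleura}
- {pattern: unremarkable, class: normal, organ: liver_gallbladder}
- {pattern: normal, class: normal, organ: liver_gallbladder}
- {pattern: unremarkable, class: normal, organ: kidneys_ureters}
- {pattern: normal, class: normal, organ: kidneys_ureters}

# --- other abnormalities (block the normal verdict) ------------------------
- {pattern: pneumothorax, class: other_abnormality, organ: lungs_pleura}
- {pattern: consolidation, class: other_abnormality, organ: lungs_pleura}
- {pattern: 'opacit*', class: other_abnormality, organ: lungs_pleura}
- {pattern: pneumonia, class: other_abnormality, organ: lungs_pleura}
- {pattern: fibrosis, class: other_abnormality, organ: lungs_pleura}
- {pattern: bronchiectasis, class: other_abnormality, organ: lungs_pleura}
- {pattern: 'cirrho*', class: other_abnormality, organ: liver_gallbladder}
- {pattern: hepatomegaly, class: other_abnormality, organ: liver_gallbladder}
- {pattern: cholecystitis, class: other_abnormality, organ: liver_gallbladder}
- {pattern: hydronephrosis, class: other_abnormality, organ: kidneys_ureters}
- {pattern: pyelonephritis, class: other_abnormality, organ: kidneys_ureters}
- {pattern: stranding, class: other_abnormality, organ: kidneys_ureters}
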