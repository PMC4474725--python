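subject,BST,LR,RF,SVM,LDA,QDA,MLP
S01,75.47,80.5,74.84,81.76,81.13,79.25,78.62
S02,71.11,70.19,68.52,71.11,70.0,70.37,70.37
S03,72.22,74.26,71.48,72.78,74.07,74.81,74.81
S04,66.23,60.96,63.6,64.04,61.4,63.16,63.6
S05,53.47,56.33,54.29,56.73,56.33,54.69,56.33
S06,56.52,56.09,51.74,51.74,56.09,54.35,57.83
S07,89.25,94.79,91.21,95.11,93.81,95.77,92.18
S08,61.9,67.77,63.37,68.13,65.57,67.03,67.4
S09,74.1,75.7,74.1,65.74,76.1,75.3,76.89
S10,54.31,53.02,49.14,52.59,59.05,57.33,51.29
S11,91.74,92.17,90.0,92.17,92.17,86.52,90.87
S12,78.37,77.55,75.92,76.73,77.96,77.96,77.14
S13,79.0,79.0,81.85,81.14,74.38,52.67,81.85
S14,51.59,61.13,53.36,57.24,62.9,38.87,58.3
S15,78.75,86.45,78.02,84.25,80.22,41.03,85.35
S16,71.49,73.68,73.68,71.05,60.96,36.84,72.81
S17,56.16,60.14,58.33,56.88,50.0,34.06,60.14
S18,51.63,56.74,52.09,57.21,54.42,33.95,59.07
S19,84.48,87.36,81.95,87.36,70.4,25.27,87.0
S20,77.12,80.81,79.34,81.55,75.65,46.49,80.44
S21,78.03,83.71,82.95,84.09,73.86,34.47,84.85
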