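dataset,classifier,variant,accuracy,sensitivity,specificity
EDA,LR,original,65.8,82.5,51.6
EDA,LR,reduced,73.5,86.4,58.8
EDA,RF,original,62.3,66,59.2
EDA,RF,reduced,72.6,74.6,70.5
EDA,KNN,original,58.3,54.8,61.2
EDA,KNN,reduced,68.5,76.1,59.8
EDA,SVM,original,56.5,16.6,90.4
EDA,SVM,reduced,60,77.7,40
HRV,LR,original,67.4,67.2,67.5
HRV,LR,reduced,77.6,73.8,82.2
HRV,RF,original,62.7,61.5,63.7
HRV,RF,reduced,75.6,77.3,73.5
HRV,KNN,original,66.1,64.3,67.7
HRV,KNN,reduced,78,77.5,78.7
HRV,SVM,original,56.8,36.1,75.3
HRV,SVM,reduced,71.6,78.1,63.6
ST,LR,original,67.3,81.9,54.8
ST,LR,reduced,72,89.4,53.6
ST,RF,original,64.5,68,61.6
ST,RF,reduced,71.6,79.9,62.7
ST,KNN,original,65.6,63.4,67.4
ST,KNN,reduced,71.7,79.9,62.9
ST,SVM,original,57.9,27.9,83.5
ST,SVM,reduced,63.9,85.8,40.7
fusion,LR,original,72.1,76.8,68.2
fusion,LR,reduced,79.6,82.4,76.5
fusion,RF,original,69,65.6,71.8
fusion,RF,reduced,78.7,81.1,76.2
fusion,KNN,original,69,65.7,71.8
fusion,KNN,reduced,77.2,78.4,76
fusion,SVM,original,68.6,59.2,76.7
fusion,SVM,reduced,81.6,81.4,81.9
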