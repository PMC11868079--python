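# Published benchmark: LOOCV balanced accuracy of seven classifiers on 13
# two-class biomedical (gene-expression and clinical) datasets.
dataset,Naive Bayes,MLP,J48,Logistic,SMO,IB1,N-Spherical
AP Endometrium Kidney,0.9860,0.5000,0.9334,0.9884,0.9860,0.9860,0.9961
AP Lung Kidney,0.9748,0.5042,0.9194,0.9707,0.9765,0.9626,0.9763
AP Endometrium Prostate,0.9691,0.4373,0.9845,0.9845,0.9855,0.9918,0.9927
AP Breast Uterus,0.9462,0.5000,0.9327,0.9528,0.9410,0.9356,0.9567
AP Breast Ovary,0.9615,0.4907,0.9254,0.9627,0.9671,0.9245,0.9414
AP Ovary Lung,0.9101,0.5129,0.9216,0.9249,0.9155,0.9057,0.9260
Brain Cancer Kaggle,0.8888,0.9722,0.8888,0.9722,0.9722,0.9444,1.0000
Lung,0.6612,0.4966,0.3911,0.6350,0.5604,0.5147,0.8534
Lymphoma,0.9327,0.9555,0.8248,0.9337,0.9327,0.7288,0.9772
Leukemia,0.8636,1.0000,0.9359,0.9359,1.0000,1.0000,1.0000
Nutt,0.7500,0.7857,0.8214,0.8928,0.9285,0.6071,0.9642
Diabetic Mellitus,0.9031,0.8806,0.9945,0.9238,0.8958,0.5981,0.9366
Covid-19 Kaggle,0.9309,0.9745,0.9812,0.9454,0.9189,0.9727,0.9911
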