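sample_id,subgroup,response,age
S001,alpha,None,44.32701691699772
S002,alpha,None,52.37141154950518
S003,alpha,Good,57.31149632241372
S004,alpha,Good,44.61891862965257
S005,alpha,Good,71.6936135937359
S006,alpha,None,65.87135769578518
S007,alpha,None,54.31929369673243
S008,alpha,None,48.85155539597013
S009,alpha,Good,31.872853394868564
S010,alpha,Good,64.92688126664528
S011,alpha,None,59.83329689559723
S012,alpha,Good,59.59284109731814
S013,alpha,Good,68.02794494605097
S014,alpha,Good,58.886085357635345
S015,alpha,Good,84.09847824562965
S016,alpha,Good,90.46992436493134
S017,beta,Good,38.77283948250651
S018,beta,None,61.28285704795999
S019,beta,Good,76.38297295600427
S020,beta,None,54.52509671983272
S021,beta,None,67.02112536340813
S022,beta,None,66.4330989417765
S023,beta,Good,94.4355198081054
S024,beta,None,23.42330093143965
S025,beta,None,43.519032348297834
S026,beta,None,47.049065551158215
S027,beta,Good,25.01140957255301
S028,beta,None,70.28119817147044
S029,beta,None,44.997200771247805
S030,beta,None,41.07443045233525
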