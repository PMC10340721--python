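/root/pkg/teststest_racc.py_oracles.pytest_mito_events.pytest_group_stats.pytest_synth_mito.pytest_acceptance.pytest_synth_vesicles.pytest_preprocess.pyconftest.pytest_pipeline_cli.pytest_vesicle_coloc.py    �   �����0��]��Q��         �   ����żz��^�7��Q��                                         �   h���0�w�;�[���Q��         �   6���żz��^�7��Q��          �    ����������/��Q��         �   �����a@oq��Q��          �   �����������/��Q��         �   i����a@oq��Q��          �   6���żz��^�7��Q��         �   ���u0,����Q��          �   ����Շ�����;��Q��         YmrA?yW S�WYmrA?yW S�W������� �   ��������      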