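import numpy as np
import pytest

from radnps import ImageFrame, NpsConfig, SyntheticSpec, gen_flat_frame

PIXEL_MM = 0.125
NYQUIST = 1.0 / (2 * PIXEL_MM)  # 4 cycles/mm


@pytest.fixture
def cfg512() -> NpsConfig:
    """Pipeline settings for 512x512 frames (4 local ROIs of 256)."""
    return NpsConfig(roi_size=512)


@pytest.fixture
def cfg256() -> NpsConfig:
    """Pipeline settings for 256x256 frames (a single local ROI)."""
    return NpsConfig(roi_size=256)


def white_frame(sigma: float, size: int, seed: int) -> ImageFrame:
    """Electronic-noise-only synthetic frame: i.i.d. Gaussian white noise."""
    spec = SyntheticSpec(
        size=size,
        spacing=PIXEL_MM,
        mean_signal=1000.0,
        quantum_gain=0.0,
        electronic_sigma=sigma,
        seed=seed,
    )
    return gen_flat_frame(spec)


def write_dicom(path, pixels: np.ndarray, spacing=None, slope=None, intercept=None,
                transfer_syntax=None):
    """Minimal single-frame monochrome DICOM writer for fixtures."""
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    pixels = np.asarray(pixels, dtype=np.uint16)
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = transfer_syntax or ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "OT"
    ds.Rows, ds.Columns = pixels.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    if spacing is not None:
        ds.PixelSpacing = [str(spacing[0]), str(spacing[1])]
    if slope is not None:
        ds.RescaleSlope = slope
        ds.RescaleIntercept = intercept
    if transfer_syntax is not None and transfer_syntax.is_compressed:
        from pydicom.encaps import encapsulate

        ds.PixelData = encapsulate([pixels.tobytes()])
        ds["PixelData"].is_undefined_length = True
    else:
        ds.PixelData = pixels.tobytes()
    pydicom.dcmwrite(path, ds, enforce_file_format=True)
    return path
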